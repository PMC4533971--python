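raw,canonical
Agriculture,agriculture
Aquaculture,aquaculture
Climate change,climate change
Coastal erosion,coastal erosion
Deforestation,deforestation
ENSO like events,ENSO like events
Erosion,erosion
Fertilizers use,fertilizers use
Fishing,fishing
NSO like events,ENSO like events
Nutrient inputs,nutrient inputs
Nutrient intputs,nutrient inputs
Ranching (livestock),ranching (livestock)
Sea surface temperature,sea surface temperature
Sediments,sediments
green house gases,greenhouse gases
upwelling,upwellings
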