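shift,driver
Eutrophication,Nutrient inputs
Eutrophication,agriculture
Eutrophication,urban storm water runoff
Marine food web simplification,Climate change
Marine food web simplification,nutrient inputs
Marine food web simplification,fishing
Hypoxia,Fertilizers use
Hypoxia,upwellings
Hypoxia,water stratification
Fisheries collapse,Fishing
Fisheries collapse,NSO like events
Fisheries collapse,upwellings
Floating plants,Fertilizers use
Floating plants,sediments
Floating plants,sewage
River channel change,Erosion
River channel change,floods
River channel change,rainfall variability
Mangroves transitions,Deforestation
Mangroves transitions,coastal erosion
Mangroves transitions,sea level rise
Sea grass transitions,Sediments
Sea grass transitions,aquaculture
Sea grass transitions,fishing
Marine eutrophication,Nutrient inputs
Marine eutrophication,climate change
Marine eutrophication,sewage
West Antarctica Ice Sheet collapse,Climate change
West Antarctica Ice Sheet collapse,sea surface temperature
West Antarctica Ice Sheet collapse,upwelling
Bivalves collapse,Aquaculture
Bivalves collapse,disease
Bivalves collapse,sediments
Coral transitions,Fishing
Coral transitions,climate change
Coral transitions,ocean acidification
Kelp transitions,ENSO like events
Kelp transitions,fishing
Kelp transitions,nutrient inputs
Encroachment,Ranching (livestock)
Encroachment,irrigation
Encroachment,fire frequency
Soil salinization,Agriculture
Soil salinization,irrigation
Soil salinization,floods
Forest to savannas,Deforestation
Forest to savannas,fire frequency
Forest to savannas,droughts
Dry land degradation,Erosion
Dry land degradation,droughts
Dry land degradation,water infrastructure
Tundra to forest,Climate change
Tundra to forest,hunting
Tundra to forest,ranching (livestock)
Monsoon,Deforestation
Monsoon,droughts
Monsoon,sea surface temperature
Peatlands,Nutrient intputs
Peatlands,precipitation
Peatlands,wetland drainage
Greenland Ice Sheet melting,Climate change
Greenland Ice Sheet melting,green house gases
Greenland Ice Sheet melting,water stratification
Thermohaline Circulation Collapse,Sea surface temperature
Thermohaline Circulation Collapse,sea water density
Thermohaline Circulation Collapse,climate change
Salt marshes to tidal flats,Coastal erosion
Salt marshes to tidal flats,nutrient inputs
Salt marshes to tidal flats,sea level rise
Arctic Sea Ice collapse,Climate change
Arctic Sea Ice collapse,green house gases
Arctic Sea Ice collapse,sea surface temperature
Steppe to tundra,Climate change
Steppe to tundra,temperature
Steppe to tundra,hunting
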