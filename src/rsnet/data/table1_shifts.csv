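shift,ecosystem_type,ecosystem_class
Eutrophication,Aquatic-Coastal,aquatic
Marine food web simplification,Aquatic-Coastal,aquatic
Hypoxia,Aquatic-Coastal,aquatic
Fisheries collapse,Aquatic-Marine,aquatic
Floating plants,Aquatic,aquatic
River channel change,Aquatic,aquatic
Mangroves transitions,Aquatic-Coastal,aquatic
Sea grass transitions,Aquatic-Coastal,aquatic
Marine eutrophication,Marine,aquatic
West Antarctica Ice Sheet collapse,Polar,subcontinental
Bivalves collapse,Marine,aquatic
Coral transitions,Marine,aquatic
Kelp transitions,Marine,aquatic
Encroachment,Savannas,terrestrial
Soil salinization,Dry lands,terrestrial
Forest to savannas,Forest-Savanna,terrestrial
Dry land degradation,Dry lands,terrestrial
Tundra to forest,Tundra,terrestrial
Monsoon,Marine-Terrestrial,subcontinental
Peatlands,Peatlands,terrestrial
Greenland Ice Sheet melting,Polar,subcontinental
Thermohaline Circulation Collapse,Polar-Marine,subcontinental
Salt marshes to tidal flats,Marine-Coastal,aquatic
Arctic Sea Ice collapse,Polar,subcontinental
Steppe to tundra,Steppe,terrestrial
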