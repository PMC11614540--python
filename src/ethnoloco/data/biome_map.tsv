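mht_category	biome6
Tropical and Subtropical Moist Broadleaf Forests	TropicalForest
Tropical and Subtropical Dry Broadleaf Forests	TropicalForest
Tropical and Subtropical Coniferous Forests	TropicalForest
Mangroves	TropicalForest
Temperate Broadleaf and Mixed Forests	TemperateForest
Temperate Conifer Forests	TemperateForest
Mediterranean Forests, Woodlands and Scrub	TemperateForest
Boreal Forests/Taiga	BorealForestTaiga
Tropical and Subtropical Grasslands, Savannas and Shrublands	Grassland
Temperate Grasslands, Savannas and Shrublands	Grassland
Flooded Grasslands and Savannas	Grassland
Montane Grasslands and Shrublands	Grassland
Deserts and Xeric Shrublands	Desert
Tundra	Tundra
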