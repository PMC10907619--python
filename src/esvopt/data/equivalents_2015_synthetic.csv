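# Per-class, per-function ESV equivalents, "2015-improved" table version
# (adds the water-supply and nutrient-cycle-maintenance functions).
# SYNTHETIC/REPRESENTATIVE values: transcribed from the widely used
# improved equivalent-factor convention (11 service functions), not an
# authoritative copy of any published table. Construction land is zero
# by convention.
version,class_code,class_name,function,category,equivalent
2015,1,cultivated,food_production,provisioning,0.85
2015,1,cultivated,raw_material,provisioning,0.40
2015,1,cultivated,water_supply,provisioning,0.02
2015,1,cultivated,gas_regulation,regulation,0.67
2015,1,cultivated,climate_regulation,regulation,0.36
2015,1,cultivated,environment_purification,regulation,0.10
2015,1,cultivated,hydrological_regulation,regulation,0.27
2015,1,cultivated,soil_conservation,support,1.03
2015,1,cultivated,nutrient_cycling,support,0.12
2015,1,cultivated,biodiversity,support,0.13
2015,1,cultivated,aesthetic_landscape,culture,0.06
2015,2,forest,food_production,provisioning,0.29
2015,2,forest,raw_material,provisioning,0.66
2015,2,forest,water_supply,provisioning,0.34
2015,2,forest,gas_regulation,regulation,2.17
2015,2,forest,climate_regulation,regulation,6.50
2015,2,forest,environment_purification,regulation,1.93
2015,2,forest,hydrological_regulation,regulation,4.74
2015,2,forest,soil_conservation,support,2.65
2015,2,forest,nutrient_cycling,support,0.20
2015,2,forest,biodiversity,support,2.41
2015,2,forest,aesthetic_landscape,culture,1.06
2015,3,grassland,food_production,provisioning,0.22
2015,3,grassland,raw_material,provisioning,0.33
2015,3,grassland,water_supply,provisioning,0.18
2015,3,grassland,gas_regulation,regulation,1.14
2015,3,grassland,climate_regulation,regulation,3.02
2015,3,grassland,environment_purification,regulation,1.00
2015,3,grassland,hydrological_regulation,regulation,2.21
2015,3,grassland,soil_conservation,support,1.39
2015,3,grassland,nutrient_cycling,support,0.11
2015,3,grassland,biodiversity,support,1.27
2015,3,grassland,aesthetic_landscape,culture,0.56
2015,4,water,food_production,provisioning,0.80
2015,4,water,raw_material,provisioning,0.23
2015,4,water,water_supply,provisioning,8.29
2015,4,water,gas_regulation,regulation,0.77
2015,4,water,climate_regulation,regulation,2.29
2015,4,water,environment_purification,regulation,5.55
2015,4,water,hydrological_regulation,regulation,102.24
2015,4,water,soil_conservation,support,0.93
2015,4,water,nutrient_cycling,support,0.07
2015,4,water,biodiversity,support,2.55
2015,4,water,aesthetic_landscape,culture,1.89
2015,5,construction,food_production,provisioning,0.00
2015,5,construction,raw_material,provisioning,0.00
2015,5,construction,water_supply,provisioning,0.00
2015,5,construction,gas_regulation,regulation,0.00
2015,5,construction,climate_regulation,regulation,0.00
2015,5,construction,environment_purification,regulation,0.00
2015,5,construction,hydrological_regulation,regulation,0.00
2015,5,construction,soil_conservation,support,0.00
2015,5,construction,nutrient_cycling,support,0.00
2015,5,construction,biodiversity,support,0.00
2015,5,construction,aesthetic_landscape,culture,0.00
2015,6,unused,food_production,provisioning,0.01
2015,6,unused,raw_material,provisioning,0.03
2015,6,unused,water_supply,provisioning,0.02
2015,6,unused,gas_regulation,regulation,0.11
2015,6,unused,climate_regulation,regulation,0.10
2015,6,unused,environment_purification,regulation,0.31
2015,6,unused,hydrological_regulation,regulation,0.21
2015,6,unused,soil_conservation,support,0.13
2015,6,unused,nutrient_cycling,support,0.01
2015,6,unused,biodiversity,support,0.12
2015,6,unused,aesthetic_landscape,culture,0.05
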