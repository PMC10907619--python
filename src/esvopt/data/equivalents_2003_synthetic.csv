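# Per-class, per-function ESV equivalents, "2003" table version.
# SYNTHETIC/REPRESENTATIVE values: transcribed from the widely used
# Chinese equivalent-factor convention (9 service functions), not an
# authoritative copy of any published table. Construction land is zero
# by convention. Equivalents are dimensionless multiples of the
# standard equivalent Ea (yuan/hm2).
version,class_code,class_name,function,category,equivalent
2003,1,cultivated,food_production,provisioning,1.00
2003,1,cultivated,raw_material,provisioning,0.10
2003,1,cultivated,gas_regulation,regulation,0.50
2003,1,cultivated,climate_regulation,regulation,0.89
2003,1,cultivated,water_regulation,regulation,0.60
2003,1,cultivated,waste_treatment,regulation,1.64
2003,1,cultivated,soil_conservation,support,1.46
2003,1,cultivated,biodiversity,support,0.71
2003,1,cultivated,recreation_culture,culture,0.01
2003,2,forest,food_production,provisioning,0.10
2003,2,forest,raw_material,provisioning,2.60
2003,2,forest,gas_regulation,regulation,3.50
2003,2,forest,climate_regulation,regulation,2.70
2003,2,forest,water_regulation,regulation,3.20
2003,2,forest,waste_treatment,regulation,1.31
2003,2,forest,soil_conservation,support,3.90
2003,2,forest,biodiversity,support,3.26
2003,2,forest,recreation_culture,culture,1.28
2003,3,grassland,food_production,provisioning,0.30
2003,3,grassland,raw_material,provisioning,0.05
2003,3,grassland,gas_regulation,regulation,0.80
2003,3,grassland,climate_regulation,regulation,0.90
2003,3,grassland,water_regulation,regulation,0.80
2003,3,grassland,waste_treatment,regulation,1.31
2003,3,grassland,soil_conservation,support,1.95
2003,3,grassland,biodiversity,support,1.09
2003,3,grassland,recreation_culture,culture,0.04
2003,4,water,food_production,provisioning,0.10
2003,4,water,raw_material,provisioning,0.01
2003,4,water,gas_regulation,regulation,0.00
2003,4,water,climate_regulation,regulation,0.46
2003,4,water,water_regulation,regulation,20.38
2003,4,water,waste_treatment,regulation,18.18
2003,4,water,soil_conservation,support,0.01
2003,4,water,biodiversity,support,2.49
2003,4,water,recreation_culture,culture,4.34
2003,5,construction,food_production,provisioning,0.00
2003,5,construction,raw_material,provisioning,0.00
2003,5,construction,gas_regulation,regulation,0.00
2003,5,construction,climate_regulation,regulation,0.00
2003,5,construction,water_regulation,regulation,0.00
2003,5,construction,waste_treatment,regulation,0.00
2003,5,construction,soil_conservation,support,0.00
2003,5,construction,biodiversity,support,0.00
2003,5,construction,recreation_culture,culture,0.00
2003,6,unused,food_production,provisioning,0.01
2003,6,unused,raw_material,provisioning,0.00
2003,6,unused,gas_regulation,regulation,0.00
2003,6,unused,climate_regulation,regulation,0.00
2003,6,unused,water_regulation,regulation,0.03
2003,6,unused,waste_treatment,regulation,0.01
2003,6,unused,soil_conservation,support,0.02
2003,6,unused,biodiversity,support,0.34
2003,6,unused,recreation_culture,culture,0.01
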