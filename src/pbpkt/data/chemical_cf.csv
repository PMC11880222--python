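name,value,units
blood_air_partition,6.85,dimensionless
partition_fat,40.0,dimensionless
partition_liver,2.5,dimensionless
partition_kidney,1.6,dimensionless
partition_richly,2.5,dimensionless
partition_slowly,0.8,dimensionless
partition_skin,1.0,dimensionless
partition_lung,1.0,dimensionless
partition_stomach_tissue,1.0,dimensionless
partition_intestine_tissue,1.0,dimensionless
vmax_c_liver1,7.0,mg/h/kg^0.75
km_liver1,0.45,mg/L
vmax_c_liver2,0.0,mg/h/kg^0.75
km_liver2,0.0,mg/L
vmax_c_lung,0.0,mg/h/kg^0.75
km_lung,0.0,mg/L
vmax_c_kidney,0.16,mg/h/kg^0.75
km_kidney,0.45,mg/L
kf_c_liver,0.0,/h
kf_c_lung,0.0,/h
kf_c_kidney,0.0,/h
kf_c_stomach,0.0,/h
kf_c_intestine,0.0,/h
oral_absorption_rate_stomach,0.6,/h
oral_absorption_rate_intestine,0.4,/h
stomach_to_intestine_rate,0.35,/h
fecal_transit_rate,0.0,/h
dermal_permeability,0.0,cm/h
urinary_clearance_c,0.0,L/h/kg^0.75
depot_release_rate,0.0,/h
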