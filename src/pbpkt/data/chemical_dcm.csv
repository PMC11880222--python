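name,value,units
blood_air_partition,9.7,dimensionless
partition_fat,14.5,dimensionless
partition_liver,1.46,dimensionless
partition_kidney,1.0,dimensionless
partition_richly,1.46,dimensionless
partition_slowly,0.82,dimensionless
partition_skin,1.0,dimensionless
partition_lung,1.46,dimensionless
partition_stomach_tissue,1.0,dimensionless
partition_intestine_tissue,1.0,dimensionless
vmax_c_liver1,4.0,mg/h/kg^0.75
km_liver1,0.4,mg/L
vmax_c_liver2,0.0,mg/h/kg^0.75
km_liver2,0.0,mg/L
vmax_c_lung,0.41,mg/h/kg^0.75
km_lung,0.4,mg/L
vmax_c_kidney,0.0,mg/h/kg^0.75
km_kidney,0.0,mg/L
kf_c_liver,1.5,/h
kf_c_lung,0.3,/h
kf_c_kidney,0.0,/h
kf_c_stomach,0.0,/h
kf_c_intestine,0.0,/h
oral_absorption_rate_stomach,1.0,/h
oral_absorption_rate_intestine,0.0,/h
stomach_to_intestine_rate,0.0,/h
fecal_transit_rate,0.0,/h
dermal_permeability,0.0,cm/h
urinary_clearance_c,0.0,L/h/kg^0.75
depot_release_rate,0.0,/h
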