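name,value,units
body_weight,70.0,kg
volume_fraction_fat,0.17,L/kg
volume_fraction_liver,0.026,L/kg
volume_fraction_kidney,0.0044,L/kg
volume_fraction_richly,0.05,L/kg
volume_fraction_slowly,0.3,L/kg
volume_fraction_skin,0.037,L/kg
volume_fraction_lung,0.008,L/kg
volume_fraction_stomach_tissue,0.005,L/kg
volume_fraction_intestine_tissue,0.014,L/kg
volume_fraction_arterial,0.0198,L/kg
volume_fraction_venous,0.0593,L/kg
flow_fraction_fat,0.052,dimensionless
flow_fraction_liver,0.227,dimensionless
flow_fraction_kidney,0.175,dimensionless
flow_fraction_richly,0.19,dimensionless
flow_fraction_slowly,0.24,dimensionless
flow_fraction_skin,0.058,dimensionless
flow_fraction_lung,0.025,dimensionless
flow_fraction_stomach_tissue,0.012,dimensionless
flow_fraction_intestine_tissue,0.021,dimensionless
cardiac_output_c,16.5,L/h/kg^0.75
alveolar_ventilation_c,24.0,L/h/kg^0.75
skin_area_c,1100.0,cm^2/kg^0.667
gas_exchange_volume,1.4,L
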