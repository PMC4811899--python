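patient_id,dosing_weight_kg,dose_mg,infusion_duration_min,tau_min,dose_number,total_doses,time_origin,sample_time_min,conc,conc_unit,excluded,note,assay_lloq_mg_l
EX-001,28.7,23.0,120.0,360.0,9,16,0,135.0,0.8,mg/L,False,,
EX-001,28.7,23.0,120.0,360.0,9,16,0,150.0,0.709,mg/L,False,,
EX-001,28.7,23.0,120.0,360.0,9,16,0,180.0,0.633,mg/L,False,,
EX-001,28.7,23.0,120.0,360.0,9,16,0,240.0,0.457,mg/L,False,,
EX-001,28.7,23.0,120.0,360.0,9,16,0,360.0,0.271,mg/L,False,,
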