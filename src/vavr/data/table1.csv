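patient_id,sex,aortic_regurgitation,height_cm,weight_kg,bsa_m2,age_years,reference_valve_size_mm,peak_systolic_flow_mls
1,F,no,164,68,1.8,69,23,354
2,M,mild,192,95,2.3,62,27,430
3,M,no,185,98,2.3,72,25,394
4,M,moderate,198,105,2.4,64,23,539
5,M,no,180,81,2.1,60,23,367
6,F,moderate,168,68,1.8,64,23,235
7,M,no,184,100,2.3,70,23,407
8,F,mild,170,70,1.9,57,21,296
9,M,no,169,88,2.1,68,25,412
10,M,no,190,110,2.4,59,25,464
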