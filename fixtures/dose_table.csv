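substance,n_products,n_mastitis,n_reproductive,n_fever,n_diarrhea,n_misc,n_herds,n_add,median_add_g_per_day,n_uadd,median_udd_mg_per_kg_day,dose_ratio
ceftriaxone,34,25,4,3,0,2,19,79.55,3.75,74.35,7.5,1.07
ceftiofur,13,2,8,1,0,2,8,45.77,0.5,22.89,1.25,2.0
cefoperazone,12,10,0,0,0,2,10,19.01,3.0,19.01,11.25,1.0
ceftizoxime,7,6,0,0,0,1,6,16.5,2.0,11.0,7.5,1.5
enrofloxacin,57,31,6,16,0,4,34,78.93,2.1,83.08,5.0,0.95
levofloxacin,2,2,0,0,0,0,2,1.6,1.85,1.78,4.0,0.9
gentamicin,18,12,0,5,0,1,13,5.69,4.2,29.95,1.8,0.19
amoxicillin,34,24,5,5,0,0,19,31.68,4.15,35.2,7.5,0.9
ampicillin,2,2,0,0,0,0,2,3.19,4.88,6.13,4.5,0.52
oxytetracycline,31,7,4,18,1,1,21,18.63,3.25,49.03,3.25,0.38
cefalexin,9,0,9,0,0,0,7,9.26,2.8,17.15,6.75,0.54
procaine benzylpenicillin,32,23,1,3,0,5,18,43.5,5.2,124.29,3.25,0.35
sulphadiazine,10,1,0,1,8,0,10,4.51,5.2,19.61,3.0,0.23
metronidazole,4,0,4,0,0,0,4,2.5,2.0,10.0,1.25,0.25
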