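productId,tradeName,formulation,unitSize,substance,concentration,concentrationUnit,role
P01,Ceftriaxone,PARENTERAL,30.0,ceftriaxone,250.0,mg/mL,
P02,Ceftiofur,PARENTERAL,30.0,ceftiofur,50.0,mg/mL,
P03,Cefoperazone,PARENTERAL,30.0,cefoperazone,250.0,mg/mL,
P04,Ceftizoxime,PARENTERAL,30.0,ceftizoxime,200.0,mg/mL,
P05,Enrofloxacin,PARENTERAL,30.0,enrofloxacin,100.0,mg/mL,
P06,Levofloxacin,PARENTERAL,30.0,levofloxacin,100.0,mg/mL,
P07,Gentamicin,PARENTERAL,30.0,gentamicin,40.0,mg/mL,
P08,Amoxicillin,PARENTERAL,30.0,amoxicillin,150.0,mg/mL,
P09,Ampicillin,PARENTERAL,30.0,ampicillin,100.0,mg/mL,
P10,Oxytetracycline,PARENTERAL,30.0,oxytetracycline,50.0,mg/mL,
P11,Cefalexin,PARENTERAL,30.0,cefalexin,100.0,mg/mL,
P12,Procaine Benzylpenicillin,PARENTERAL,30.0,procaine benzylpenicillin,200.0,mg/mL,
P13,Sulphadiazine,PARENTERAL,30.0,sulphadiazine,200.0,mg/mL,
P14,Metronidazole,PARENTERAL,30.0,metronidazole,50.0,mg/mL,
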