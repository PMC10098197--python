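substance,species,route,dddKg_mg_per_kg_day,source
ceftriaxone,BOVINE_ANY,PARENTERAL,7.009345794392523,BACKCALC
ceftiofur,BOVINE_ANY,PARENTERAL,0.625,BACKCALC
cefoperazone,BOVINE_ANY,PARENTERAL,11.25,BACKCALC
ceftizoxime,BOVINE_ANY,PARENTERAL,5.0,BACKCALC
enrofloxacin,BOVINE_ANY,PARENTERAL,5.2631578947368425,BACKCALC
levofloxacin,BOVINE_ANY,PARENTERAL,4.444444444444445,BACKCALC
gentamicin,BOVINE_ANY,PARENTERAL,9.473684210526315,BACKCALC
amoxicillin,BOVINE_ANY,PARENTERAL,8.333333333333334,BACKCALC
ampicillin,BOVINE_ANY,PARENTERAL,8.653846153846153,BACKCALC
oxytetracycline,BOVINE_ANY,PARENTERAL,8.552631578947368,BACKCALC
cefalexin,BOVINE_ANY,PARENTERAL,12.5,BACKCALC
procaine benzylpenicillin,BOVINE_ANY,PARENTERAL,9.285714285714286,BACKCALC
sulphadiazine,BOVINE_ANY,PARENTERAL,13.043478260869565,BACKCALC
metronidazole,BOVINE_ANY,PARENTERAL,5.0,BACKCALC
trimethoprim,BOVINE_ANY,PARENTERAL,4.0,LABEL
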