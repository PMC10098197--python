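substance,amClass
ceftriaxone,cephalosporins-3rd-gen
ceftiofur,cephalosporins-3rd-gen
cefoperazone,cephalosporins-3rd-gen
ceftizoxime,cephalosporins-3rd-gen
enrofloxacin,quinolones
levofloxacin,quinolones
gentamicin,aminoglycosides
amoxicillin,aminopenicillins
ampicillin,aminopenicillins
oxytetracycline,tetracyclines
cefalexin,cephalosporins-1st-gen
procaine benzylpenicillin,penicillins
benzylpenicillin,penicillins
benzathine benzylpenicillin,penicillins
sulphadiazine,sulphonamides
sulphadimethoxine,sulphonamides
metronidazole,nitroimidazole
trimethoprim,diaminopyrimidines
clavulanic acid,beta-lactamase-inhibitors
sulbactam,beta-lactamase-inhibitors
tazobactam,beta-lactamase-inhibitors
procaine,excipients
benzathine,excipients
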