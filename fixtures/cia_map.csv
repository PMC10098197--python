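amClass,whoCategory
cephalosporins-3rd-gen,HPCIA
quinolones,HPCIA
aminopenicillins,HIGH_PRIORITY_CIA
aminoglycosides,HIGH_PRIORITY_CIA
tetracyclines,HIGHLY_IMPORTANT
cephalosporins-1st-gen,HIGHLY_IMPORTANT
penicillins,HIGHLY_IMPORTANT
sulphonamides,HIGHLY_IMPORTANT
nitroimidazole,IMPORTANT
diaminopyrimidines,HIGHLY_IMPORTANT
beta-lactamase-inhibitors,UNCLASSIFIED
excipients,UNCLASSIFIED
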