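herdId,herdType,nCattle,nBuffalo,enrolmentDays
H01,HOUSEHOLD,7,5,365
H02,HOUSEHOLD,7,6,365
H03,HOUSEHOLD,7,5,365
H04,HOUSEHOLD,7,6,365
H05,HOUSEHOLD,7,5,365
H06,HOUSEHOLD,7,6,365
H07,HOUSEHOLD,7,5,365
H08,HOUSEHOLD,7,6,365
H09,HOUSEHOLD,7,5,365
H10,HOUSEHOLD,7,6,365
H11,HOUSEHOLD,7,5,365
H12,HOUSEHOLD,7,6,365
H13,HOUSEHOLD,7,5,365
H14,HOUSEHOLD,7,6,365
H15,HOUSEHOLD,7,5,365
H16,HOUSEHOLD,7,6,365
H17,HOUSEHOLD,7,5,365
H18,HOUSEHOLD,7,6,365
H19,HOUSEHOLD,7,5,365
H20,HOUSEHOLD,7,6,365
H21,COMMERCIAL,22,21,365
H22,COMMERCIAL,21,22,365
H23,COMMERCIAL,21,22,365
H24,COMMERCIAL,21,22,365
H25,COMMERCIAL,21,21,365
H26,COMMERCIAL,21,21,365
H27,COMMERCIAL,21,21,365
H28,COMMERCIAL,21,21,365
H29,COMMERCIAL,21,21,365
H30,COMMERCIAL,21,21,365
H31,COMMERCIAL,21,21,365
H32,COMMERCIAL,21,21,365
H33,COMMERCIAL,21,21,365
H34,COMMERCIAL,21,21,365
H35,COMMERCIAL,21,21,365
H36,COMMERCIAL,21,21,365
H37,COMMERCIAL,21,21,365
H38,COMMERCIAL,21,21,365
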