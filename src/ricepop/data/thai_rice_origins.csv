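origin,POP1,POP2,POP3,POP4,POP5
North,4,5,7,0,29
North-East,1,14,37,0,1
Central,21,15,19,2,0
South,0,0,0,89,2
IRRI indica,7,1,0,0,0
IRRI Tropical japonica,1,2,0,0,2
IRRI Aus,0,3,0,0,0
IRRI Temperate japonica,0,0,0,0,4
IRRI Aromatic,0,0,0,0,3
Unknown,19,5,5,1,1
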