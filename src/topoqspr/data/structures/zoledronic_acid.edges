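# Zoledronic Acid: hydrogen-suppressed molecular graph (standard-structure)
O1 C2
C2 C3
C3 N4
N4 C5
C5 C6
C6 N7
N7 C8
C2 P9
P9 O10
P9 O11
P9 O12
C2 P13
P13 O14
P13 O15
P13 O16
C8 N4
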