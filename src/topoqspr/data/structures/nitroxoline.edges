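# Nitroxoline: hydrogen-suppressed molecular graph (standard-structure)
O1 N2
N2 O3
N2 C4
C4 C5
C5 C6
C6 C7
C7 O8
C7 C9
C9 N10
N10 C11
C11 C12
C12 C13
C13 C14
C14 C4
C14 C9
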