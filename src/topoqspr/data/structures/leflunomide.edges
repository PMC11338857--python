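# Leflunomide: hydrogen-suppressed molecular graph (standard-structure)
C1 C2
C2 O3
O3 N4
N4 C5
C5 C6
C6 C7
C7 O8
C7 N9
N9 C10
C10 C11
C11 C12
C12 C13
C13 C14
C14 F15
C14 F16
C14 F17
C13 C18
C18 C19
C6 C2
C19 C10
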