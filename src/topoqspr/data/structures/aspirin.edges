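# Aspirin: hydrogen-suppressed molecular graph (standard-structure)
C1 C2
C2 O3
C2 O4
O4 C5
C5 C6
C6 C7
C7 C8
C8 C9
C9 C10
C10 C11
C11 O12
C11 O13
C10 C5
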