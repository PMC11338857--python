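# Metformin: hydrogen-suppressed molecular graph (standard-structure)
C1 N2
N2 C3
N2 C4
C4 N5
C4 N6
N6 C7
C7 N8
C7 N9
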