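# Valproic Acid: hydrogen-suppressed molecular graph (standard-structure)
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C7
C4 C8
C8 O9
C8 O10
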