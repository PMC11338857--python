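# Thalidomide: hydrogen-suppressed molecular graph (standard-structure)
O1 C2
C2 C3
C3 C4
C4 C5
C5 N6
N6 C7
C7 O8
C7 C9
C9 C10
C10 C11
C11 C12
C12 C13
C13 C14
C14 C15
C15 O16
C5 C17
C17 O18
C17 N19
N19 C2
C15 N6
C14 C9
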