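# Celecoxib: hydrogen-suppressed molecular graph (standard-structure)
C1 C2
C2 C3
C3 C4
C4 C5
C5 C6
C6 C7
C7 C8
C8 C9
C9 F10
C9 F11
C9 F12
C8 N13
N13 N14
N14 C15
C15 C16
C16 C17
C17 C18
C18 S19
S19 N20
S19 O21
S19 O22
C18 C23
C23 C24
C5 C25
C25 C26
C26 C2
N14 C6
C24 C15
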