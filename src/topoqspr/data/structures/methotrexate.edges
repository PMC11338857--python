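# Methotrexate: hydrogen-suppressed molecular graph (standard-structure)
C1 N2
N2 C3
C3 C4
C4 C5
C5 N6
N6 C7
C7 N8
N8 C9
C9 N10
C9 N11
N11 C12
C12 N13
C12 C14
C14 N15
N2 C16
C16 C17
C17 C18
C18 C19
C19 C20
C20 O21
C20 N22
N22 C23
C23 C24
C24 C25
C25 C26
C26 O27
C26 O28
C23 C29
C29 O30
C29 O31
C19 C32
C32 C33
N15 C4
C33 C16
C14 C7
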