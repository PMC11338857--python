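{
 "name": "Celecoxib",
 "file": "celecoxib.edges",
 "smiles": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
 "provenance": "standard-structure"
}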