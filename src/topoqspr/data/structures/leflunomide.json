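{
 "name": "Leflunomide",
 "file": "leflunomide.edges",
 "smiles": "Cc1oncc1C(=O)Nc1ccc(C(F)(F)F)cc1",
 "provenance": "standard-structure"
}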