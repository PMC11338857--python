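{
 "name": "Thalidomide",
 "file": "thalidomide.edges",
 "smiles": "O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1",
 "provenance": "standard-structure"
}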