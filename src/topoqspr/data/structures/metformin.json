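{
 "name": "Metformin",
 "file": "metformin.edges",
 "smiles": "CN(C)C(=N)NC(=N)N",
 "provenance": "standard-structure"
}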