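{
 "name": "Zoledronic Acid",
 "file": "zoledronic_acid.edges",
 "smiles": "OC(Cn1ccnc1)(P(=O)(O)O)P(=O)(O)O",
 "provenance": "standard-structure"
}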