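{
 "name": "Valproic Acid",
 "file": "valproic_acid.edges",
 "smiles": "CCCC(CCC)C(=O)O",
 "provenance": "standard-structure"
}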