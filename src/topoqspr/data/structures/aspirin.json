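{
 "name": "Aspirin",
 "file": "aspirin.edges",
 "smiles": "CC(=O)Oc1ccccc1C(=O)O",
 "provenance": "standard-structure"
}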