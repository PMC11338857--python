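{
 "name": "Nitroxoline",
 "file": "nitroxoline.edges",
 "smiles": "O=[N+]([O-])c1ccc(O)c2ncccc12",
 "provenance": "standard-structure"
}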