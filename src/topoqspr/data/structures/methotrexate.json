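{
 "name": "Methotrexate",
 "file": "methotrexate.edges",
 "smiles": "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1",
 "provenance": "standard-structure"
}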