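{
 "gene": "CSNK2B",
 "uniprot_accession": "P67870",
 "protein_length": 215
}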