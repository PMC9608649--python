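{
 "gene": "CSNK2A1",
 "uniprot_accession": "P68400",
 "protein_length": 391
}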