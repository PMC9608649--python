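{
 "Benign": "benign",
 "Neutral": "benign",
 "Tolerated": "benign",
 "Non-disease causing": "benign",
 "Polymorphism": "benign",
 "Stabilizing": "benign",
 "Possibly Damaging": "effect",
 "Probably Damaging": "effect",
 "Damaging": "effect",
 "Deleterious": "effect",
 "Not Tolerated": "effect",
 "Disease Causing": "effect",
 "Disease": "effect",
 "Effect": "effect",
 "Low": "effect",
 "Medium": "effect",
 "High": "effect",
 "Destabilizing": "effect"
}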