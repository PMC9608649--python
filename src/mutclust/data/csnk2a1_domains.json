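{
 "gene": "CSNK2A1",
 "domains": [
  {
   "name": "N-terminal segment",
   "ranges": [
    [
     1,
     39
    ]
   ]
  },
  {
   "name": "Gly-rich loop",
   "ranges": [
    [
     46,
     51
    ]
   ]
  },
  {
   "name": "Polybasic stretch",
   "ranges": [
    [
     74,
     80
    ]
   ]
  },
  {
   "name": "Hinge plus alphaD",
   "ranges": [
    [
     113,
     128
    ]
   ]
  },
  {
   "name": "Catalytic loop",
   "ranges": [
    [
     154,
     161
    ]
   ]
  },
  {
   "name": "Activation segment",
   "ranges": [
    [
     175,
     201
    ]
   ]
  },
  {
   "name": "CK2beta binding",
   "ranges": [
    [
     36,
     73
    ],
    [
     103,
     108
    ]
   ]
  },
  {
   "name": "ATP binding",
   "ranges": [
    [
     46,
     51
    ]
   ],
   "residues": [
    66,
    114,
    115,
    116,
    163,
    174
   ]
  },
  {
   "name": "Mg2+ binding loop",
   "ranges": [
    [
     175,
     177
    ]
   ]
  },
  {
   "name": "Activation loop",
   "ranges": [
    [
     178,
     190
    ]
   ]
  },
  {
   "name": "P+1 loop",
   "ranges": [
    [
     191,
     201
    ]
   ]
  },
  {
   "name": "Phosphorylation sites",
   "residues": [
    13,
    182,
    255,
    344,
    360,
    362,
    370
   ]
  }
 ]
}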