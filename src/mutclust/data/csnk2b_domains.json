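{
 "gene": "CSNK2B",
 "domains": [
  {
   "name": "N-terminal segment",
   "ranges": [
    [
     1,
     54
    ]
   ]
  },
  {
   "name": "Phosphorylation sites",
   "residues": [
    2,
    3,
    4,
    209,
    213
   ]
  },
  {
   "name": "Destruction box",
   "ranges": [
    [
     47,
     54
    ]
   ]
  },
  {
   "name": "Acidic loop",
   "ranges": [
    [
     55,
     70
    ]
   ]
  },
  {
   "name": "Zinc-finger",
   "ranges": [
    [
     106,
     146
    ]
   ]
  },
  {
   "name": "Cys bound to Zinc",
   "residues": [
    109,
    114,
    137,
    140
   ]
  },
  {
   "name": "CK2beta/CK2beta contact region",
   "ranges": [
    [
     110,
     205
    ]
   ]
  },
  {
   "name": "Interface to CK2alpha 1",
   "ranges": [
    [
     164,
     170
    ]
   ]
  },
  {
   "name": "Interface to CK2alpha 2",
   "ranges": [
    [
     186,
     198
    ]
   ]
  },
  {
   "name": "C-terminal segment",
   "ranges": [
    [
     179,
     215
    ]
   ]
  }
 ]
}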