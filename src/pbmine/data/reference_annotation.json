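{
 "clades": {
  "A": {
   "consensus_id": "PBcons_A",
   "triad": [
    250,
    340,
    440
   ],
   "insertion": [
    380,
    400
   ],
   "crd_cys": [
    522,
    527,
    533,
    541,
    546,
    554,
    559
   ],
   "trp": 462,
   "domains": {
    "NTD": [
     0,
     100
    ],
    "DDBD1": [
     100,
     230
    ],
    "DDD": [
     230,
     460
    ],
    "DDBD2": [
     460,
     520
    ],
    "CRD": [
     520,
     580
    ]
   }
  },
  "B": {
   "consensus_id": "PBcons_B",
   "triad": [
    250,
    340,
    440
   ],
   "insertion": [
    380,
    400
   ],
   "crd_cys": [
    522,
    527,
    533,
    541,
    546,
    554,
    559
   ],
   "trp": 462,
   "domains": {
    "NTD": [
     0,
     100
    ],
    "DDBD1": [
     100,
     230
    ],
    "DDD": [
     230,
     460
    ],
    "DDBD2": [
     460,
     520
    ],
    "CRD": [
     520,
     580
    ]
   }
  },
  "C": {
   "consensus_id": "PBcons_C",
   "triad": [
    250,
    340,
    440
   ],
   "insertion": [
    380,
    400
   ],
   "crd_cys": [
    522,
    527,
    533,
    541,
    546,
    554,
    559
   ],
   "trp": 462,
   "domains": {
    "NTD": [
     0,
     100
    ],
    "DDBD1": [
     100,
     230
    ],
    "DDD": [
     230,
     460
    ],
    "DDBD2": [
     460,
     520
    ],
    "CRD": [
     520,
     580
    ]
   }
  }
 }
}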