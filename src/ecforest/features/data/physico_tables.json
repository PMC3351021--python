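{
 "dayhoff_freq": {
  "A": 8.6,
  "C": 2.9,
  "D": 5.5,
  "E": 6.0,
  "F": 3.6,
  "G": 8.4,
  "H": 2.0,
  "I": 4.5,
  "K": 6.6,
  "L": 7.4,
  "M": 1.7,
  "N": 4.3,
  "P": 5.2,
  "Q": 3.9,
  "R": 4.9,
  "S": 7.0,
  "T": 6.1,
  "V": 6.6,
  "W": 1.3,
  "Y": 3.4
 },
 "elemental": {
  "A": [
   3,
   7,
   1,
   2,
   0
  ],
  "C": [
   3,
   7,
   1,
   2,
   1
  ],
  "D": [
   4,
   7,
   1,
   4,
   0
  ],
  "E": [
   5,
   9,
   1,
   4,
   0
  ],
  "F": [
   9,
   11,
   1,
   2,
   0
  ],
  "G": [
   2,
   5,
   1,
   2,
   0
  ],
  "H": [
   6,
   9,
   3,
   2,
   0
  ],
  "I": [
   6,
   13,
   1,
   2,
   0
  ],
  "K": [
   6,
   14,
   2,
   2,
   0
  ],
  "L": [
   6,
   13,
   1,
   2,
   0
  ],
  "M": [
   5,
   11,
   1,
   2,
   1
  ],
  "N": [
   4,
   8,
   2,
   3,
   0
  ],
  "P": [
   5,
   9,
   1,
   2,
   0
  ],
  "Q": [
   5,
   10,
   2,
   3,
   0
  ],
  "R": [
   6,
   14,
   4,
   2,
   0
  ],
  "S": [
   3,
   7,
   1,
   3,
   0
  ],
  "T": [
   4,
   9,
   1,
   3,
   0
  ],
  "V": [
   5,
   11,
   1,
   2,
   0
  ],
  "W": [
   11,
   12,
   2,
   2,
   0
  ],
  "Y": [
   9,
   11,
   1,
   3,
   0
  ]
 },
 "elemental_order": [
  "C",
  "H",
  "N",
  "O",
  "S"
 ],
 "kyte_doolittle": {
  "A": 1.8,
  "C": 2.5,
  "D": -3.5,
  "E": -3.5,
  "F": 2.8,
  "G": -0.4,
  "H": -3.2,
  "I": 4.5,
  "K": -3.9,
  "L": 3.8,
  "M": 1.9,
  "N": -3.5,
  "P": -1.6,
  "Q": -3.5,
  "R": -4.5,
  "S": -0.8,
  "T": -0.7,
  "V": 4.2,
  "W": -0.9,
  "Y": -1.3
 },
 "pka_sets": {
  "bjellqvist": {
   "C": 9.0,
   "D": 4.05,
   "E": 4.45,
   "H": 5.98,
   "K": 10.0,
   "R": 12.0,
   "Y": 10.0,
   "cterm": 3.55,
   "cterm_by_residue": {
    "D": 4.55,
    "E": 4.75
   },
   "nterm": 7.5,
   "nterm_by_residue": {
    "A": 7.59,
    "E": 7.7,
    "M": 7.0,
    "P": 8.36,
    "S": 6.93,
    "T": 6.82,
    "V": 7.44
   }
  },
  "emboss": {
   "C": 8.5,
   "D": 3.9,
   "E": 4.1,
   "H": 6.5,
   "K": 10.8,
   "R": 12.5,
   "Y": 10.1,
   "cterm": 3.6,
   "cterm_by_residue": {},
   "nterm": 8.6,
   "nterm_by_residue": {}
  }
 },
 "property_classes": {
  "acidic": [
   "D",
   "E"
  ],
  "aliphatic": [
   "I",
   "L",
   "V"
  ],
  "aromatic": [
   "F",
   "H",
   "W",
   "Y"
  ],
  "basic": [
   "H",
   "K",
   "R"
  ],
  "charged": [
   "D",
   "E",
   "H",
   "K",
   "R"
  ],
  "non_polar": [
   "A",
   "C",
   "F",
   "G",
   "I",
   "L",
   "M",
   "P",
   "V",
   "W",
   "Y"
  ],
  "polar": [
   "D",
   "E",
   "H",
   "K",
   "N",
   "Q",
   "R",
   "S",
   "T"
  ],
  "small": [
   "A",
   "C",
   "D",
   "G",
   "N",
   "P",
   "S",
   "T",
   "V"
  ],
  "tiny": [
   "A",
   "C",
   "G",
   "S",
   "T"
  ]
 },
 "residue_avg_mass": {
  "A": 89.0932,
  "C": 121.1582,
  "D": 133.1027,
  "E": 147.1293,
  "F": 165.1891,
  "G": 75.0666,
  "H": 155.1546,
  "I": 131.1729,
  "K": 146.1876,
  "L": 131.1729,
  "M": 149.2113,
  "N": 132.1179,
  "P": 115.1305,
  "Q": 146.1445,
  "R": 174.201,
  "S": 105.0926,
  "T": 119.1192,
  "V": 117.1463,
  "W": 204.2252,
  "Y": 181.1885
 },
 "residue_charge": {
  "A": 0.0,
  "C": 0.0,
  "D": -1.0,
  "E": -1.0,
  "F": 0.0,
  "G": 0.0,
  "H": 0.5,
  "I": 0.0,
  "K": 1.0,
  "L": 0.0,
  "M": 0.0,
  "N": 0.0,
  "P": 0.0,
  "Q": 0.0,
  "R": 1.0,
  "S": 0.0,
  "T": 0.0,
  "V": 0.0,
  "W": 0.0,
  "Y": 0.0
 },
 "version": "1",
 "water_atoms": [
  0,
  2,
  0,
  1,
  0
 ],
 "water_mass": 18.0153
}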