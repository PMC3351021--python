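{
 "version": "73-v1",
 "features": [
  {
   "name": "mole_percent_A",
   "kind": "composition"
  },
  {
   "name": "mole_percent_C",
   "kind": "composition"
  },
  {
   "name": "mole_percent_D",
   "kind": "composition"
  },
  {
   "name": "mole_percent_E",
   "kind": "composition"
  },
  {
   "name": "mole_percent_F",
   "kind": "composition"
  },
  {
   "name": "mole_percent_G",
   "kind": "composition"
  },
  {
   "name": "mole_percent_H",
   "kind": "composition"
  },
  {
   "name": "mole_percent_I",
   "kind": "composition"
  },
  {
   "name": "mole_percent_K",
   "kind": "composition"
  },
  {
   "name": "mole_percent_L",
   "kind": "composition"
  },
  {
   "name": "mole_percent_M",
   "kind": "composition"
  },
  {
   "name": "mole_percent_N",
   "kind": "composition"
  },
  {
   "name": "mole_percent_P",
   "kind": "composition"
  },
  {
   "name": "mole_percent_Q",
   "kind": "composition"
  },
  {
   "name": "mole_percent_R",
   "kind": "composition"
  },
  {
   "name": "mole_percent_S",
   "kind": "composition"
  },
  {
   "name": "mole_percent_T",
   "kind": "composition"
  },
  {
   "name": "mole_percent_V",
   "kind": "composition"
  },
  {
   "name": "mole_percent_W",
   "kind": "composition"
  },
  {
   "name": "mole_percent_Y",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_A",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_C",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_D",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_E",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_F",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_G",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_H",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_I",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_K",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_L",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_M",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_N",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_P",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_Q",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_R",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_S",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_T",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_V",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_W",
   "kind": "composition"
  },
  {
   "name": "dayhoff_stat_Y",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_acidic",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_aliphatic",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_aromatic",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_basic",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_charged",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_non_polar",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_polar",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_small",
   "kind": "composition"
  },
  {
   "name": "class_mole_percent_tiny",
   "kind": "composition"
  },
  {
   "name": "class_count_acidic",
   "kind": "composition"
  },
  {
   "name": "class_count_aliphatic",
   "kind": "composition"
  },
  {
   "name": "class_count_aromatic",
   "kind": "composition"
  },
  {
   "name": "class_count_basic",
   "kind": "composition"
  },
  {
   "name": "class_count_charged",
   "kind": "composition"
  },
  {
   "name": "class_count_non_polar",
   "kind": "composition"
  },
  {
   "name": "class_count_polar",
   "kind": "composition"
  },
  {
   "name": "class_count_small",
   "kind": "composition"
  },
  {
   "name": "class_count_tiny",
   "kind": "composition"
  },
  {
   "name": "length",
   "kind": "global"
  },
  {
   "name": "molecular_weight",
   "kind": "global"
  },
  {
   "name": "charge",
   "kind": "composition"
  },
  {
   "name": "theoretical_pi",
   "kind": "composition"
  },
  {
   "name": "negative_residue_count",
   "kind": "composition"
  },
  {
   "name": "positive_residue_count",
   "kind": "composition"
  },
  {
   "name": "atoms_C",
   "kind": "composition"
  },
  {
   "name": "atoms_H",
   "kind": "composition"
  },
  {
   "name": "atoms_N",
   "kind": "composition"
  },
  {
   "name": "atoms_O",
   "kind": "composition"
  },
  {
   "name": "atoms_S",
   "kind": "composition"
  },
  {
   "name": "gravy",
   "kind": "composition"
  },
  {
   "name": "aliphatic_index",
   "kind": "composition"
  },
  {
   "name": "instability_index",
   "kind": "order"
  },
  {
   "name": "extinction_coefficient_cystine",
   "kind": "composition"
  }
 ]
}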