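{
 "pepA": {
  "sequence": "MKVLA",
  "molecular_weight": 560.7501000000001,
  "isoelectric_point_bjellqvist": 8.500108146667483,
  "gravy": 1.56,
  "instability_index": -8.98,
  "extinction_reduced": 0,
  "extinction_cystine": 0,
  "aromaticity": 0.0
 },
 "pepB": {
  "sequence": "MKWVTFISLLLLFSSAYSRGVCDECCH",
  "molecular_weight": 3109.661699999999,
  "isoelectric_point_bjellqvist": 6.494445991516113,
  "gravy": 0.7333333333333334,
  "instability_index": 54.51481481481481,
  "extinction_reduced": 6990,
  "extinction_cystine": 7115,
  "aromaticity": 0.14814814814814814
 }
}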