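{
  "version": "NIST-2021/CODATA-2018",
  "electron_mass_da": 0.000548579909,
  "elements": {
    "H":  [[1.00782503207, 0.999885], [2.01410177785, 0.000115]],
    "C":  [[12.0, 0.9893], [13.00335483507, 0.0107]],
    "N":  [[14.0030740048, 0.99636], [15.0001088982, 0.00364]],
    "O":  [[15.9949146196, 0.99757], [16.9991317012, 0.00038], [17.9991610043, 0.00205]],
    "Na": [[22.9897692809, 1.0]],
    "P":  [[30.97376163, 1.0]],
    "S":  [[31.97207100, 0.9499], [32.97145876, 0.0075], [33.96786690, 0.0425], [35.96708076, 0.0001]],
    "Cl": [[34.96885268, 0.7576], [36.96590259, 0.2424]]
  }
}
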