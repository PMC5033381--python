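{
  "composition": {"Glc": 2, "Gal": 2, "GalA": 1, "6dTal": 1},
  "pmaa": [
    {"sugar": "Glc", "positions": [], "detectable": true, "abundance": 1.0},
    {"sugar": "Glc", "positions": [4], "detectable": true, "abundance": 1.0},
    {"sugar": "dHex", "positions": [4], "detectable": true, "abundance": 0.8},
    {"sugar": "Gal", "positions": [4], "detectable": true, "abundance": 0.6},
    {"sugar": "Gal", "positions": [2, 4], "detectable": true, "abundance": 1.0},
    {"sugar": "GalA", "positions": [4], "detectable": false}
  ],
  "fragments": [
    {"name": "os211",
     "composition": {"Hex": 2, "HexA": 1, "dHex": 1},
     "reducing_end": "Hex"},
    {"name": "os311a",
     "composition": {"Hex": 3, "HexA": 1, "dHex": 1},
     "reducing_end": "Hex",
     "y_compositions": [{"Hex": 2}, {"Hex": 3}]},
    {"name": "os411a",
     "composition": {"Hex": 4, "HexA": 1, "dHex": 1},
     "reducing_end": "Hex",
     "b_prefix": ["Hex", "dHex"],
     "y_compositions": [{"Hex": 2}, {"Hex": 3}, {"Hex": 3, "HexA": 1}]},
    {"name": "os411b",
     "composition": {"Hex": 4, "HexA": 1, "dHex": 1},
     "reducing_end": "dHex"}
  ],
  "adjacencies": [
    {"donor": "HexA", "acceptor": "Hex"}
  ],
  "hmbc": [
    {"donor": "Glc", "position": 4, "acceptor": "6dTal",
     "donor_substitutions": [4], "acceptor_substitutions": [4]},
    {"donor": "6dTal", "position": 4, "acceptor": "GalA",
     "donor_substitutions": [4], "acceptor_substitutions": [4]},
    {"donor": "Gal", "position": 4, "acceptor": "Gal",
     "donor_substitutions": [4], "acceptor_substitutions": [2, 4]},
    {"donor": "Glc", "position": 2, "acceptor": "Gal",
     "donor_substitutions": [], "acceptor_substitutions": [2, 4]}
  ]
}
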