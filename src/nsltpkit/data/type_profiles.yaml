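# Default nsLTP type profiles: allowed inter-cysteine gap ranges (g1..g5,
# the five free gaps of the 8CM), expected intron counts of the coding
# region, and whether a GPI anchor is expected.  The ranges follow the
# spacing conventions of the Edstam-style classification literature; they
# are configuration, not ground truth, and can be replaced wholesale.
"1":
  gaps: [[8, 10], [13, 16], [18, 21], [20, 24], [12, 14]]
  introns: [1]
  gpi: false
"2":
  gaps: [[6, 8], [12, 14], [7, 10], [21, 24], [4, 7]]
  introns: [0]
  gpi: false
"C":
  gaps: [[9, 11], [14, 16], [11, 13], [25, 28], [6, 8]]
  introns: [1]
  gpi: false
"D":
  gaps: [[8, 10], [11, 15], [8, 11], [25, 29], [12, 16]]
  introns: [0, 1]
  gpi: false
"E":
  gaps: [[7, 9], [9, 12], [14, 17], [17, 20], [8, 10]]
  introns: [1]
  gpi: false
"F":
  gaps: [[10, 12], [16, 18], [12, 15], [18, 20], [9, 11]]
  introns: [1]
  gpi: false
"G":
  gaps: [[8, 10], [13, 16], [18, 22], [20, 25], [12, 15]]
  introns: [2]
  gpi: true
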