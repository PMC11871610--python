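{
  "_comment": "Background amino-acid frequency distributions for conservation scoring. 'blosum62' are the marginal frequencies underlying the BLOSUM62 substitution matrix.",
  "blosum62": {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073
  },
  "uniform": {
    "A": 0.05, "R": 0.05, "N": 0.05, "D": 0.05, "C": 0.05,
    "Q": 0.05, "E": 0.05, "G": 0.05, "H": 0.05, "I": 0.05,
    "L": 0.05, "K": 0.05, "M": 0.05, "F": 0.05, "P": 0.05,
    "S": 0.05, "T": 0.05, "W": 0.05, "Y": 0.05, "V": 0.05
  }
}
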