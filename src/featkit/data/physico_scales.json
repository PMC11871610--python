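{
  "_comment": "Per-residue physicochemical property scales over the 20 standard amino acids. Keys are scale names with a literature tag; each scale maps one-letter residue codes to published values.",
  "scales": {
    "hydropathy_kyte_doolittle_1982": {
      "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
      "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
      "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
    },
    "hydrophilicity_hopp_woods_1981": {
      "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
      "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
      "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5
    },
    "hydrophobicity_consensus_eisenberg_1984": {
      "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.9, "C": 0.29, "Q": -0.85, "E": -0.74,
      "G": 0.48, "H": -0.4, "I": 1.38, "L": 1.06, "K": -1.5, "M": 0.64, "F": 1.19,
      "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08
    },
    "hydrophobicity_fauchere_pliska_1983": {
      "A": 0.31, "R": -1.01, "N": -0.6, "D": -0.77, "C": 1.54, "Q": -0.22, "E": -0.64,
      "G": 0.0, "H": 0.13, "I": 1.8, "L": 1.7, "K": -0.99, "M": 1.23, "F": 1.79,
      "P": 0.72, "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22
    },
    "hydrophobicity_black_mould_1991": {
      "A": 0.616, "R": 0.0, "N": 0.236, "D": 0.028, "C": 0.68, "Q": 0.251, "E": 0.043,
      "G": 0.501, "H": 0.165, "I": 0.943, "L": 0.943, "K": 0.283, "M": 0.738, "F": 1.0,
      "P": 0.711, "S": 0.359, "T": 0.45, "W": 0.878, "Y": 0.88, "V": 0.825
    },
    "hydrophobicity_miyazawa_jernigan_1985": {
      "A": 5.33, "R": 4.18, "N": 3.71, "D": 3.59, "C": 7.93, "Q": 3.87, "E": 3.65,
      "G": 4.48, "H": 5.1, "I": 8.83, "L": 8.47, "K": 2.95, "M": 8.95, "F": 9.03,
      "P": 3.87, "S": 4.09, "T": 4.49, "W": 7.66, "Y": 5.89, "V": 7.63
    },
    "hydrophilicity_parker_1986": {
      "A": 2.1, "R": 4.2, "N": 7.0, "D": 10.0, "C": 1.4, "Q": 6.0, "E": 7.8,
      "G": 5.7, "H": 2.1, "I": -8.0, "L": -9.2, "K": 5.7, "M": -4.2, "F": -9.2,
      "P": 2.1, "S": 6.5, "T": 5.2, "W": -10.0, "Y": -1.9, "V": -3.7
    },
    "transfer_energy_engelman_ges_1986": {
      "A": 1.6, "R": -12.3, "N": -4.8, "D": -9.2, "C": 2.0, "Q": -4.1, "E": -8.2,
      "G": 1.0, "H": -3.0, "I": 3.1, "L": 2.8, "K": -8.8, "M": 3.4, "F": 3.7,
      "P": -0.2, "S": 0.6, "T": 1.2, "W": 1.9, "Y": -0.7, "V": 2.6
    },
    "interface_scale_wimley_white_1996": {
      "A": -0.17, "R": -0.81, "N": -0.42, "D": -1.23, "C": 0.24, "Q": -0.58, "E": -2.02,
      "G": -0.01, "H": -0.17, "I": 0.31, "L": 0.56, "K": -0.99, "M": 0.23, "F": 1.13,
      "P": -0.45, "S": -0.13, "T": -0.14, "W": 1.85, "Y": 0.94, "V": -0.07
    },
    "buried_preference_janin_1979": {
      "A": 0.3, "R": -1.4, "N": -0.5, "D": -0.6, "C": 0.9, "Q": -0.7, "E": -0.7,
      "G": 0.3, "H": -0.1, "I": 0.7, "L": 0.5, "K": -1.8, "M": 0.4, "F": 0.5,
      "P": -0.3, "S": -0.1, "T": -0.2, "W": 0.3, "Y": -0.4, "V": 0.6
    },
    "mean_fractional_area_buried_rose_1985": {
      "A": 0.74, "R": 0.64, "N": 0.63, "D": 0.62, "C": 0.91, "Q": 0.62, "E": 0.62,
      "G": 0.72, "H": 0.78, "I": 0.88, "L": 0.85, "K": 0.52, "M": 0.85, "F": 0.88,
      "P": 0.64, "S": 0.66, "T": 0.7, "W": 0.85, "Y": 0.76, "V": 0.86
    },
    "polarity_grantham_1974": {
      "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
      "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
      "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9
    },
    "polarity_zimmerman_1968": {
      "A": 0.0, "R": 52.0, "N": 3.38, "D": 49.7, "C": 1.48, "Q": 3.53, "E": 49.9,
      "G": 0.0, "H": 51.6, "I": 0.13, "L": 0.13, "K": 49.5, "M": 1.43, "F": 0.35,
      "P": 1.58, "S": 1.67, "T": 1.66, "W": 2.1, "Y": 1.61, "V": 0.13
    },
    "bulkiness_zimmerman_1968": {
      "A": 11.5, "R": 14.28, "N": 12.82, "D": 11.68, "C": 13.46, "Q": 14.45, "E": 13.57,
      "G": 3.4, "H": 13.69, "I": 21.4, "L": 21.4, "K": 15.71, "M": 16.25, "F": 19.8,
      "P": 17.43, "S": 9.47, "T": 15.77, "W": 21.67, "Y": 18.03, "V": 21.57
    },
    "polarizability_charton_charton_1982": {
      "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128, "Q": 0.18, "E": 0.151,
      "G": 0.0, "H": 0.23, "I": 0.186, "L": 0.186, "K": 0.219, "M": 0.221, "F": 0.29,
      "P": 0.131, "S": 0.062, "T": 0.108, "W": 0.409, "Y": 0.298, "V": 0.14
    },
    "refractivity_jones_1975": {
      "A": 4.34, "R": 26.66, "N": 13.28, "D": 12.0, "C": 35.77, "Q": 17.56, "E": 17.26,
      "G": 0.0, "H": 21.81, "I": 19.06, "L": 18.78, "K": 21.29, "M": 21.64, "F": 29.4,
      "P": 10.93, "S": 6.35, "T": 11.01, "W": 42.53, "Y": 31.53, "V": 13.92
    },
    "residue_volume_zamyatnin_1972": {
      "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8, "E": 138.4,
      "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9,
      "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0
    },
    "normalized_vdw_volume_fauchere_1988": {
      "A": 1.0, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43, "Q": 3.95, "E": 3.78,
      "G": 0.0, "H": 4.66, "I": 4.0, "L": 4.0, "K": 4.77, "M": 4.43, "F": 5.89,
      "P": 2.72, "S": 1.6, "T": 2.6, "W": 8.08, "Y": 6.47, "V": 3.0
    },
    "molecular_weight": {
      "A": 89.09, "R": 174.2, "N": 132.12, "D": 133.1, "C": 121.16, "Q": 146.15, "E": 147.13,
      "G": 75.07, "H": 155.16, "I": 131.17, "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19,
      "P": 115.13, "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15
    },
    "isoelectric_point": {
      "A": 6.0, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65, "E": 3.22,
      "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48,
      "P": 6.3, "S": 5.68, "T": 5.6, "W": 5.89, "Y": 5.66, "V": 5.96
    },
    "net_charge_ph7": {
      "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0, "Q": 0.0, "E": -1.0,
      "G": 0.0, "H": 0.1, "I": 0.0, "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0,
      "P": 0.0, "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0
    },
    "flexibility_bhaskaran_ponnuswamy_1988": {
      "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493, "E": 0.497,
      "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466, "M": 0.295, "F": 0.314,
      "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305, "Y": 0.42, "V": 0.386
    },
    "helix_propensity_chou_fasman_1978": {
      "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.7, "Q": 1.11, "E": 1.51,
      "G": 0.57, "H": 1.0, "I": 1.08, "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13,
      "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06
    },
    "sheet_propensity_chou_fasman_1978": {
      "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.1, "E": 0.37,
      "G": 0.75, "H": 0.87, "I": 1.6, "L": 1.3, "K": 0.74, "M": 1.05, "F": 1.38,
      "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.7
    },
    "turn_propensity_chou_fasman_1978": {
      "A": 0.66, "R": 0.95, "N": 1.56, "D": 1.46, "C": 1.19, "Q": 0.98, "E": 0.74,
      "G": 1.56, "H": 0.95, "I": 0.47, "L": 0.59, "K": 1.01, "M": 0.6, "F": 0.6,
      "P": 1.52, "S": 1.43, "T": 0.96, "W": 0.96, "Y": 1.14, "V": 0.5
    }
  }
}
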