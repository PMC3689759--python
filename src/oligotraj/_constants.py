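"""Physical constants and element tables shared across modules."""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K = 1.987e-3

#: Coulomb prefactor giving kcal/mol for charges in e and distances in A.
COULOMB_KCAL_A_E2 = 332.0636

#: Average atomic masses (amu) for elements common in proteins.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "BR": 79.904,
    "I": 126.904,
}

#: Average residue masses (amu, residue = amino acid minus water) for the
#: twenty standard amino acids; used by the synthetic generator to give its
#: side-chain pseudo-atom a realistic mass.
RESIDUE_MASSES = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}

#: One-letter to three-letter amino-acid codes.
AA_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "P": "PRO", "V": "VAL", "T": "THR",
    "C": "CYS", "L": "LEU", "I": "ILE", "N": "ASN", "D": "ASP", "Q": "GLN",
    "K": "LYS", "E": "GLU", "M": "MET", "H": "HIS", "F": "PHE", "R": "ARG",
    "Y": "TYR", "W": "TRP",
}
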