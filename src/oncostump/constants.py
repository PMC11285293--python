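"""Shared constants: residue alphabet, background frequencies, feature schemas."""

# Canonical one-letter amino-acid codes in fixed (alphabetical) order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"
UNKNOWN = "X"
MSA_ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}

# BLOSUM62 amino-acid background frequencies (Henikoff & Henikoff), ordered
# as AMINO_ACIDS.  Used as the default background q for divergence scoring.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}

DOMAIN_LABELS = ("cytoplasmic", "extracellular", "transmembrane", "other")

# Canonical feature schemas.  SEQ features are computable from sequence
# information alone; STR appends the structure-derived block.
SEQ_FEATURES = (
    "essential",
    "cons_grade",
    "msa_score",
    "dom_cytoplasmic",
    "dom_extracellular",
    "dom_transmembrane",
    "dom_other",
    "predictsnp",
    "n_essential",
)
STR_FEATURES = SEQ_FEATURES + (
    "foldx_ddg",
    "rosetta_ddg",
    "in_pocket",
    "pka_max_up",
    "pka_max_down",
    "pka_mean_abs",
)

MODES = ("SEQ", "STR")

N_GRADES = 9

MODEL_SCHEMA = "stump-ensemble/1"
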