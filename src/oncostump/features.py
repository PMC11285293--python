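"""Assembly of per-variant feature vectors.

Each missense variant is encoded as a fixed-width numeric vector.  Nine
features are computable from sequence information alone (SEQ mode):

* essentiality of the mutated residue (1/0),
* conservation grade (1-9) and raw conservation score at the position,
* one-hot domain location (cytoplasmic / extracellular / transmembrane / other),
* the consensus deleteriousness (PredictSNP-style) score in [-1, 1],
* the number of essential residues in the protein.

STR mode appends six structure-derived features: FoldX and Rosetta folding
stability changes, pocket membership (1/0), and three summaries of the pKa
shifts of essential residues between the wild-type and mutant structures
(largest rise, largest drop, mean absolute change).

The vocabulary of four domain labels, the feature order, and the split into
SEQ and STR variants mirror the curated training data; structural features
are never imputed — an STR request with a missing structural annotation is
a hard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import AMINO_ACIDS, DOMAIN_LABELS, MODES, SEQ_FEATURES, STR_FEATURES
from .errors import ModeError
from .conservation import ConservationProfile

__all__ = [
    "VariantSpec",
    "AnnotationBundle",
    "FeatureVector",
    "LigandDelta",
    "encode_domain",
    "pka_delta_features",
    "in_pocket",
    "assemble_features",
    "ligand_deltas",
]

logger = logging.getLogger(__name__)

_STRUCTURAL_FIELDS = ("foldx_ddg", "rosetta_ddg", "pocket_residues", "wt_pka", "mut_pka")


@dataclass(frozen=True)
class VariantSpec:
    """One missense mutation: 1-based UniProt position, WT and mutant residue."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based numbering)")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-canonical residue code {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise ValueError("wild-type and mutant residues must differ")

    @property
    def code(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class AnnotationBundle:
    """All per-variant external inputs.

    Structural fields (ddG scores, pockets, pKa maps) are jointly present
    (STR mode) or jointly absent (SEQ mode).
    """

    essential_residues: frozenset[int] | set[int]
    domain_label: str
    predictsnp_score: float
    n_essential: int | None = None
    foldx_ddg: float | None = None
    rosetta_ddg: float | None = None
    pocket_residues: list[set[int]] | None = None
    wt_pka: dict[int, float] | None = None
    mut_pka: dict[int, float] | None = None

    def __post_init__(self):
        self.essential_residues = frozenset(self.essential_residues)
        if self.n_essential is None:
            self.n_essential = len(self.essential_residues)
        elif self.n_essential != len(self.essential_residues):
            raise ValueError(
                "n_essential disagrees with the essential residue set"
            )
        if not -1.0 <= self.predictsnp_score <= 1.0:
            raise ValueError("predictsnp_score must lie in [-1, 1]")
        present = [f for f in _STRUCTURAL_FIELDS if getattr(self, f) is not None]
        if present and len(present) != len(_STRUCTURAL_FIELDS):
            missing = [f for f in _STRUCTURAL_FIELDS if getattr(self, f) is None]
            raise ModeError(f"structural annotations incomplete; missing: {missing}")

    @property
    def has_structure(self) -> bool:
        return self.foldx_ddg is not None


@dataclass
class FeatureVector:
    """Encoded numeric vector with its parallel feature names."""

    values: np.ndarray
    names: list[str]
    mode: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = SEQ_FEATURES if self.mode == "SEQ" else STR_FEATURES
        if len(self.values) != len(expected) or list(self.names) != list(expected):
            raise ValueError(f"feature vector does not match the {self.mode} schema")


@dataclass(frozen=True)
class LigandDelta:
    """Mutation impact on one ligand's best docking energy (kcal/mol)."""

    ligand_id: str
    e_wt: float
    e_mut: float

    @property
    def delta(self) -> float:
        return self.e_mut - self.e_wt


def encode_domain(label: str) -> np.ndarray:
    """One-hot encode the domain location, fixed order, case-insensitive."""
    key = label.strip().lower()
    if key not in DOMAIN_LABELS:
        raise ValueError(
            f"unknown domain label {label!r}; expected one of {list(DOMAIN_LABELS)}"
        )
    vec = np.zeros(4)
    vec[DOMAIN_LABELS.index(key)] = 1.0
    return vec


def pka_delta_features(
    wt_pka: dict[int, float],
    mut_pka: dict[int, float],
    essential_residues,
) -> tuple[float, float, float]:
    """Summaries of pKa shifts at essential residues.

    Over essential positions ionisable in both structures, with
    delta_i = pKa_mut(i) - pKa_wt(i): returns (largest rise, largest drop,
    mean absolute change).  All zero when no essential residue is ionisable
    in both maps (flagged in the log, not an error).
    """
    deltas = [
        mut_pka[pos] - wt_pka[pos]
        for pos in sorted(essential_residues)
        if pos in wt_pka and pos in mut_pka
    ]
    if not deltas:
        logger.info("no essential residue ionisable in both structures; pKa features are 0")
        return 0.0, 0.0, 0.0
    arr = np.asarray(deltas)
    return (
        float(max(0.0, arr.max())),
        float(max(0.0, -arr.min())),
        float(np.abs(arr).mean()),
    )


def in_pocket(position: int, pockets: list[set[int]] | None) -> int:
    """1 iff the position belongs to any predicted binding pocket."""
    if not pockets:
        return 0
    return int(any(position in pocket for pocket in pockets))


def assemble_features(
    variant: VariantSpec,
    bundle: AnnotationBundle,
    profile: ConservationProfile,
    mode: str,
) -> FeatureVector:
    """Build the SEQ (9) or STR (15) feature vector for one variant.

    Pure and deterministic: identical inputs give bit-identical vectors.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 1 <= variant.position <= profile.length:
        raise ValueError(
            f"variant position {variant.position} outside conservation profile "
            f"of length {profile.length}"
        )
    idx = variant.position - 1
    values = [
        float(variant.position in bundle.essential_residues),
        float(profile.grades[idx]),
        float(profile.scores[idx]),
        *encode_domain(bundle.domain_label),
        float(bundle.predictsnp_score),
        float(bundle.n_essential),
    ]
    if mode == "STR":
        missing = [f for f in _STRUCTURAL_FIELDS if getattr(bundle, f) is None]
        if missing:
            raise ModeError(f"STR mode requires structural annotations: missing {missing}")
        values.extend(
            [
                float(bundle.foldx_ddg),
                float(bundle.rosetta_ddg),
                float(in_pocket(variant.position, bundle.pocket_residues)),
                *pka_delta_features(bundle.wt_pka, bundle.mut_pka, bundle.essential_residues),
            ]
        )
    names = list(SEQ_FEATURES if mode == "SEQ" else STR_FEATURES)
    return FeatureVector(values=np.asarray(values), names=names, mode=mode)


def ligand_deltas(
    wt_scores: dict[str, float],
    mut_scores: dict[str, float],
) -> tuple[list[LigandDelta], list[str]]:
    """Per-ligand mutant-minus-wild-type binding-energy changes, ranked.

    Returns (deltas sorted ascending — most improved mutant binding first,
    ties broken by ligand id; ligands present in only one map).  Zero
    shared ligands is an error.
    """
    shared = sorted(set(wt_scores) & set(mut_scores))
    if not shared:
        raise ValueError("wild-type and mutant score maps share no ligand")
    unmatched = sorted(set(wt_scores) ^ set(mut_scores))
    deltas = [LigandDelta(lig, wt_scores[lig], mut_scores[lig]) for lig in shared]
    deltas.sort(key=lambda d: (d.delta, d.ligand_id))
    return deltas, unmatched
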