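"""Per-column conservation scoring of a protein multiple sequence alignment.

A column's residue distribution p is compared against a background
distribution q with the Jensen-Shannon divergence (base-2 logarithms, so the
score lies in [0, 1]):

    JSD(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m),   m = (p + q) / 2.

Highly conserved columns concentrate probability on few residues and diverge
strongly from the background.  The raw column score is down-weighted by the
gap fraction, optionally smoothed over a short window of neighbouring
columns, and finally rank-binned into nine grades (grade 9 = most
conserved).  The mutability grade commonly reported alongside is simply
``10 - conservation_grade``.

The default background is the BLOSUM62 amino-acid frequency vector; a
uniform background is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .constants import AA_INDEX, AMINO_ACIDS, BLOSUM62_BACKGROUND, GAP, N_GRADES, UNKNOWN
from .io import Msa

__all__ = [
    "blosum62_background",
    "uniform_background",
    "ColumnDistribution",
    "ConservationProfile",
    "column_distribution",
    "jsd",
    "conservation_scores",
    "grade_positions",
    "mutability_grades",
    "compute_profile",
    "filter_homologs",
]

DEFAULT_PSEUDOCOUNT = 1e-6
DEFAULT_WINDOW = 3
DEFAULT_WINDOW_WEIGHT = 0.5


def blosum62_background() -> np.ndarray:
    q = np.array([BLOSUM62_BACKGROUND[aa] for aa in AMINO_ACIDS])
    return q / q.sum()


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


@dataclass
class ColumnDistribution:
    """Pseudocounted residue frequencies of one alignment column."""

    probs: np.ndarray          # 20-vector over AMINO_ACIDS order
    gap_fraction: float
    all_gap: bool = False      # flagged, not an error

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        assert self.probs.shape == (20,)


@dataclass
class ConservationProfile:
    """Per-column scores and 1-9 grades for a whole alignment."""

    scores: np.ndarray
    grades: np.ndarray
    background: np.ndarray
    window: int

    def __post_init__(self):
        if len(self.scores) != len(self.grades):
            raise ValueError("scores and grades must be parallel")

    @property
    def length(self) -> int:
        return len(self.scores)


def column_distribution(msa: Msa, col: int, pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        background: np.ndarray | None = None) -> ColumnDistribution:
    """Residue distribution of column ``col``.

    'X' residues are excluded from both the counts and the normaliser; an
    all-gap column falls back to the background distribution and is flagged.
    """
    if not 0 <= col < msa.length:
        raise ValueError(f"column {col} outside alignment of length {msa.length}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    column = msa.column(col)
    counts = np.zeros(20)
    n_gap = 0
    n_nongap = 0
    for ch in column:
        if ch == GAP:
            n_gap += 1
        elif ch == UNKNOWN:
            continue
        else:
            counts[AA_INDEX[ch]] += 1
            n_nongap += 1
    gap_fraction = n_gap / len(column)
    if n_nongap == 0:
        q = background if background is not None else blosum62_background()
        return ColumnDistribution(probs=q.copy(), gap_fraction=gap_fraction, all_gap=True)
    probs = (counts + pseudocount) / (n_nongap + 20.0 * pseudocount)
    return ColumnDistribution(probs=probs, gap_fraction=gap_fraction)


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits; symmetric and bounded in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6 or (v < 0).any():
            raise ValueError(f"{name} is not a probability vector (sum={v.sum()})")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log2(np.where(p > 0, p / m, 1.0)), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log2(np.where(q > 0, q / m, 1.0)), 0.0).sum()
    return float(0.5 * kl_pm + 0.5 * kl_qm)


def conservation_scores(
    msa: Msa,
    background: np.ndarray | None = None,
    window: int = DEFAULT_WINDOW,
    window_weight: float = DEFAULT_WINDOW_WEIGHT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Gap-weighted, window-smoothed JSD score per alignment column.

    raw_c = (1 - gap_fraction_c) * JSD(p_c, q); the final score blends the
    raw score with the window mean centred on the column (truncated at the
    alignment ends) and is clipped to [0, 1].
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    if window > msa.length:
        raise ValueError(f"window {window} exceeds alignment length {msa.length}")
    if not 0.0 <= window_weight < 1.0 + 1e-12:
        raise ValueError("window_weight must lie in [0, 1]")
    q = background if background is not None else blosum62_background()
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("background is not a probability vector")

    raw = np.empty(msa.length)
    for c in range(msa.length):
        dist = column_distribution(msa, c, pseudocount, background=q)
        raw[c] = 0.0 if dist.all_gap else (1.0 - dist.gap_fraction) * jsd(dist.probs, q)

    if window == 1 or window_weight == 0.0:
        return np.clip(raw, 0.0, 1.0)

    half = window // 2
    smoothed = np.empty_like(raw)
    for c in range(len(raw)):
        lo, hi = max(0, c - half), min(len(raw), c + half + 1)
        smoothed[c] = raw[lo:hi].mean()
    return np.clip((1.0 - window_weight) * raw + window_weight * smoothed, 0.0, 1.0)


def grade_positions(scores, n_grades: int = N_GRADES) -> np.ndarray:
    """Equal-frequency rank binning of scores into 1..n_grades.

    Grade 1 marks the least conserved positions and n_grades the most
    conserved; tied scores share the grade of their mean rank, so a fully
    flat profile collapses onto the middle grade.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot grade an empty score list")
    ranks = rankdata(scores, method="average")  # mean rank for ties
    grades = np.floor(n_grades * (ranks - 0.5) / scores.size).astype(int) + 1
    return np.clip(grades, 1, n_grades)


def mutability_grades(conservation_grades) -> np.ndarray:
    """Mutability grade = 10 - conservation grade (high = easily mutable)."""
    return (N_GRADES + 1) - np.asarray(conservation_grades, dtype=int)


def compute_profile(
    msa: Msa,
    background: np.ndarray | None = None,
    window: int = DEFAULT_WINDOW,
    window_weight: float = DEFAULT_WINDOW_WEIGHT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ConservationProfile:
    """Scores + grades in one pass; the usual entry point."""
    q = background if background is not None else blosum62_background()
    scores = conservation_scores(msa, q, window, window_weight, pseudocount)
    return ConservationProfile(
        scores=scores,
        grades=grade_positions(scores),
        background=q,
        window=window,
    )


def filter_homologs(msa: Msa, query_index: int = 0, min_identity: float = 0.5,
                    coverage_band: float = 0.2) -> Msa:
    """Keep homologs with sufficient identity and coverage to the query.

    Identity is computed over columns where both the query and the homolog
    are non-gap; coverage compares non-gap lengths and must lie within
    ``1 +/- coverage_band`` of the query's.  The query row is always kept.
    """
    query = msa.rows[query_index]
    q_len = sum(ch != GAP for ch in query)
    keep_ids, keep_rows = [], []
    for i, (rid, row) in enumerate(zip(msa.ids, msa.rows)):
        if i == query_index:
            keep_ids.append(rid)
            keep_rows.append(row)
            continue
        both = [(a, b) for a, b in zip(query, row) if a != GAP and b != GAP]
        identity = (sum(a == b for a, b in both) / len(both)) if both else 0.0
        r_len = sum(ch != GAP for ch in row)
        coverage_ok = q_len * (1 - coverage_band) <= r_len <= q_len * (1 + coverage_band)
        if identity > min_identity and coverage_ok:
            keep_ids.append(rid)
            keep_rows.append(row)
    return Msa(ids=keep_ids, rows=keep_rows)


def write_profile_tsv(profile: ConservationProfile, path) -> None:
    """Per-position TSV: position (1-based), score, conservation grade."""
    with open(path, "w") as fh:
        fh.write("position\tscore\tgrade\n")
        for i, (s, g) in enumerate(zip(profile.scores, profile.grades), start=1):
            fh.write(f"{i}\t{s!r}\t{g}\n")
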