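"""Synthetic labeled datasets and raw-input fixtures.

The generator emulates the structure of the curated oncogenicity training
data: two partitions (SEQ with 509 oncogenic / 564 benign rows, STR with
377 / 76), rows keyed by (protein, position) with several positions carrying
more than one mutation, and class-conditional feature distributions in which
the consensus deleteriousness score and the conservation features carry the
strongest signal.

``effect_size`` scales every class separation (continuous mean shifts in
units of the feature's spread, and the gap between the class-conditional
Bernoulli rates of the binary features), so ``effect_size=0`` yields
identical class distributions and chance-level classifiers, while the
default ``effect_size=2`` gives a strongly but not perfectly separable
problem.  ``label_noise`` makes each row, independently, draw its features
from the opposite class while keeping its label — mislabeled examples —
so the configured class counts stay exact.

:func:`generate_raw_fixtures` additionally writes a full bundle of raw
input files (alignment FASTA, stability/pKa/pocket/docking tool outputs and
an annotation table) together with the feature matrix the real pipeline is
expected to reproduce from them, closing the parse -> conserve -> featurize
loop end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, DOMAIN_LABELS, SEQ_FEATURES, STR_FEATURES
from .conservation import compute_profile
from .features import AnnotationBundle, VariantSpec, assemble_features
from .io import LabeledDataset, Msa, write_msa

__all__ = [
    "SyntheticConfig",
    "generate_dataset",
    "FixtureBundle",
    "generate_raw_fixtures",
    "write_foldx_text",
    "write_rosetta_text",
    "write_propka_text",
    "write_p2rank_text",
    "write_docking_text",
]

# Class-conditional Bernoulli rates at the reference effect size (2.0):
# (oncogenic, benign).
_ESSENTIAL_RATES = (0.6, 0.1)
_POCKET_RATES = (0.5, 0.2)
_REFERENCE_EFFECT = 2.0

# Continuous features: (benign mean, sd, standardized-shift multiplier).
# The deleterious direction is "up" for every feature below.
_CONTINUOUS = {
    "msa_score": (0.35, 0.18, 0.9),
    "cons_grade": (4.5, 1.8, 0.9),
    "predictsnp": (-0.35, 0.35, 1.0),
    "foldx_ddg": (0.2, 1.2, 0.6),
    "rosetta_ddg": (0.3, 2.0, 0.6),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_oncogenic: int = 509
    n_benign: int = 564
    mode: str = "SEQ"
    n_proteins: int = 44
    positions_per_protein: int = 15
    effect_size: float = 2.0
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("SEQ", "STR"):
            raise ValueError(f"mode must be SEQ or STR, got {self.mode!r}")
        if min(self.n_oncogenic, self.n_benign, self.n_proteins,
               self.positions_per_protein) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")
        if not (self.effect_size >= 0.0 and math.isfinite(self.effect_size)):
            raise ValueError("effect_size must be finite and >= 0")


def str_default_config(**overrides) -> SyntheticConfig:
    """STR-partition defaults: 377 oncogenic / 76 benign rows."""
    base = dict(n_oncogenic=377, n_benign=76, mode="STR")
    base.update(overrides)
    return SyntheticConfig(**base)


def _rate(pair: tuple[float, float], oncogenic: np.ndarray, effect: float) -> np.ndarray:
    onc, ben = pair
    gap = (onc - ben) * min(effect / _REFERENCE_EFFECT, 1.5)
    rate = ben + np.where(oncogenic, gap, 0.0)
    return np.clip(rate, 0.0, 1.0)


def _continuous(name: str, oncogenic: np.ndarray, effect: float,
                rng: np.random.Generator) -> np.ndarray:
    mean, sd, mult = _CONTINUOUS[name]
    shift = np.where(oncogenic, effect * mult * sd, 0.0)
    return mean + shift + sd * rng.standard_normal(len(oncogenic))


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Draw one labeled SEQ/STR dataset; bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_oncogenic + config.n_benign
    labels = np.zeros(n, dtype=int)
    labels[: config.n_oncogenic] = 1
    labels = rng.permutation(labels)
    # label noise: a noisy row keeps its label but draws its features from
    # the opposite class, so the class counts stay exactly as configured
    flips = rng.random(n) < config.label_noise
    onc = (labels == 1) ^ flips

    # per-protein properties
    protein_ids = [f"P{i:02d}" for i in range(config.n_proteins)]
    domain_choice = rng.choice(4, size=config.n_proteins, p=[0.55, 0.15, 0.15, 0.15])
    n_essential = rng.integers(5, 20, size=config.n_proteins)

    # group keys: positions sampled with replacement so that some
    # (protein, position) keys collect several mutations
    prot_idx = rng.integers(0, config.n_proteins, size=n)
    pos = rng.integers(1, config.positions_per_protein + 1, size=n)
    groups = [(protein_ids[p], int(q)) for p, q in zip(prot_idx, pos)]

    e = config.effect_size
    essential = rng.random(n) < _rate(_ESSENTIAL_RATES, onc, e)
    cons_grade = np.clip(np.rint(_continuous("cons_grade", onc, e, rng)), 1, 9)
    msa_score = np.clip(_continuous("msa_score", onc, e, rng), 0.0, 1.0)
    predictsnp = np.clip(_continuous("predictsnp", onc, e, rng), -1.0, 1.0)
    domain = np.zeros((n, 4))
    domain[np.arange(n), domain_choice[prot_idx]] = 1.0

    columns = [
        essential.astype(float),
        cons_grade,
        msa_score,
        domain[:, 0], domain[:, 1], domain[:, 2], domain[:, 3],
        predictsnp,
        n_essential[prot_idx].astype(float),
    ]
    names = list(SEQ_FEATURES)

    if config.mode == "STR":
        foldx = _continuous("foldx_ddg", onc, e, rng)
        rosetta = _continuous("rosetta_ddg", onc, e, rng)
        pocket = (rng.random(n) < _rate(_POCKET_RATES, onc, e)).astype(float)
        # summaries of a small set of per-residue pKa shifts, wider for
        # oncogenic rows in proportion to the effect size
        scale = 0.2 * (1.0 + np.where(onc, 0.5 * e, 0.0))
        k = rng.integers(1, 4, size=n)
        pka_up = np.zeros(n)
        pka_down = np.zeros(n)
        pka_abs = np.zeros(n)
        for i in range(n):
            deltas = scale[i] * rng.standard_normal(k[i])
            pka_up[i] = max(0.0, deltas.max())
            pka_down[i] = max(0.0, -deltas.min())
            pka_abs[i] = np.abs(deltas).mean()
        columns.extend([foldx, rosetta, pocket, pka_up, pka_down, pka_abs])
        names = list(STR_FEATURES)

    return LabeledDataset(
        matrix=np.column_stack(columns),
        labels=labels,
        groups=groups,
        feature_names=names,
        mode=config.mode,
    )


# ---------------------------------------------------------------------------
# raw-input fixture bundles


def write_foldx_text(runs: dict[str, list[float]]) -> str:
    """FoldX stability-scan dialect: one line per run, codes repeat."""
    lines = ["# FoldX stability scan", "mutation\tddG"]
    for code, values in runs.items():
        for v in values:
            lines.append(f"{code}\t{v!r}")
    return "\n".join(lines) + "\n"


def write_rosetta_text(ddgs: dict[str, float]) -> str:
    return "".join(f"ddG: {code} {v!r}\n" for code, v in ddgs.items())


def write_propka_text(pkas: dict[int, float]) -> str:
    lines = [
        "propka3.4 prediction",
        "",
        "SUMMARY OF THIS PREDICTION",
        "     Group      pKa  model-pKa",
    ]
    for pos in sorted(pkas):
        lines.append(f"   ASP {pos:4d} A   {pkas[pos]:6.2f}     3.80")
    lines.append("-" * 40)
    return "\n".join(lines) + "\n"


def write_p2rank_text(pockets: list[set[int]]) -> str:
    lines = ["name,rank,score,residue_ids"]
    for i, pocket in enumerate(pockets, start=1):
        ids = " ".join(f"A_{p}" for p in sorted(pocket))
        lines.append(f"pocket{i},{i},{10.0 - i:.1f},{ids}")
    return "\n".join(lines) + "\n"


def write_docking_text(scores: dict[str, list[float]]) -> str:
    """Vina-style blocks: ``Ligand: <id>`` then ``<mode> <energy> rmsd rmsd``."""
    lines = []
    for ligand, poses in scores.items():
        lines.append(f"Ligand: {ligand}")
        lines.append("mode |   affinity | dist from best mode")
        for mode, energy in enumerate(poses, start=1):
            lines.append(f"   {mode}   {float(energy)!r}   0.000   0.000")
        lines.append("")
    return "\n".join(lines) + "\n"


@dataclass
class FixtureBundle:
    """Paths of a generated raw-input bundle plus its expected features."""

    root: Path
    annotations: Path
    expected: LabeledDataset
    wt_docking: Path | None = None
    mut_docking: Path | None = None
    msa_paths: dict[str, Path] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _homolog(query: str, rng: np.random.Generator, sub_rate=0.3, gap_rate=0.05) -> str:
    out = []
    for ch in query:
        r = rng.random()
        if r < gap_rate:
            out.append("-")
        elif r < gap_rate + sub_rate:
            out.append(rng.choice(list(AMINO_ACIDS)))
        else:
            out.append(ch)
    return "".join(out)


def generate_raw_fixtures(config: SyntheticConfig, out_dir,
                          protein_length: int = 40, n_homologs: int = 8) -> FixtureBundle:
    """Write a raw-input bundle and the feature matrix it must reproduce.

    One directory per protein holds the alignment and (in STR mode) the
    external-tool outputs; a top-level annotation table lists the variants.
    The expected matrix is assembled in memory from the same objects the
    files encode, so running the files through the parsers, the conservation
    scorer and the feature assembler must give the identical matrix.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_total = config.n_oncogenic + config.n_benign
    per_protein = max(1, math.ceil(n_total / config.n_proteins))

    rows, labels, groups, ann_records = [], [], [], []
    msa_paths: dict[str, Path] = {}
    n_made = 0
    for p in range(config.n_proteins):
        if n_made >= n_total:
            break
        protein = f"P{p:02d}"
        pdir = out_dir / protein
        pdir.mkdir(exist_ok=True)

        query = _random_protein(rng, protein_length)
        msa = Msa(
            ids=[f"{protein}_query"] + [f"{protein}_h{i}" for i in range(n_homologs)],
            rows=[query] + [_homolog(query, rng) for _ in range(n_homologs)],
        )
        write_msa(msa, pdir / "msa.fasta")
        msa_paths[protein] = pdir / "msa.fasta"
        profile = compute_profile(msa)

        n_ess = int(rng.integers(3, 7))
        essential = set(int(x) + 1 for x in rng.choice(protein_length, size=n_ess, replace=False))
        domain = DOMAIN_LABELS[int(rng.choice(4, p=[0.55, 0.15, 0.15, 0.15]))]

        pockets = None
        wt_pka = None
        foldx_runs: dict[str, list[float]] = {}
        rosetta: dict[str, float] = {}
        if config.mode == "STR":
            pockets = [
                set(int(x) + 1 for x in rng.choice(protein_length, size=6, replace=False)),
                set(int(x) + 1 for x in rng.choice(protein_length, size=4, replace=False)),
            ]
            (pdir / "pockets.csv").write_text(write_p2rank_text(pockets))
            ionisable = sorted(essential | set(
                int(x) + 1 for x in rng.choice(protein_length, size=5, replace=False)
            ))
            wt_pka = {pos: float(np.round(rng.uniform(2.0, 12.0), 2)) for pos in ionisable}
            (pdir / "wt.propka").write_text(write_propka_text(wt_pka))

        n_here = min(per_protein, n_total - n_made)
        positions = rng.choice(protein_length, size=n_here, replace=True) + 1
        for pos in positions:
            pos = int(pos)
            wt_aa = query[pos - 1]
            mut_aa = rng.choice([a for a in AMINO_ACIDS if a != wt_aa])
            variant = VariantSpec(protein, pos, wt_aa, mut_aa)
            label = int(rng.random() < config.n_oncogenic / n_total)

            kwargs = {}
            if config.mode == "STR":
                runs = [float(np.round(v, 4)) for v in rng.normal(0.5, 1.0, size=5)]
                foldx_runs[variant.code] = runs
                rosetta[variant.code] = float(np.round(rng.normal(0.5, 1.5), 4))
                mut_pka = {
                    pos_i: float(np.round(v + rng.normal(0.0, 0.3), 2))
                    for pos_i, v in wt_pka.items()
                }
                (pdir / f"{variant.code}.propka").write_text(write_propka_text(mut_pka))
                kwargs = dict(
                    foldx_ddg=float(np.mean(sorted(runs))),  # parser's order-free mean
                    rosetta_ddg=rosetta[variant.code],
                    pocket_residues=pockets,
                    wt_pka=wt_pka,
                    mut_pka=mut_pka,
                )
            bundle = AnnotationBundle(
                essential_residues=essential,
                domain_label=domain,
                predictsnp_score=float(np.round(rng.uniform(-1.0, 1.0), 3)),
                **kwargs,
            )
            fv = assemble_features(variant, bundle, profile, config.mode)
            rows.append(fv.values)
            labels.append(label)
            groups.append((protein, pos))
            ann_records.append(
                {
                    "protein": protein,
                    "position": pos,
                    "wt_aa": wt_aa,
                    "mut_aa": mut_aa,
                    "domain": domain,
                    "predictsnp": bundle.predictsnp_score,
                    "essential_residues": " ".join(str(x) for x in sorted(essential)),
                    "label": "Oncogenic" if label else "Benign",
                }
            )
            n_made += 1

        if config.mode == "STR":
            (pdir / "foldx.txt").write_text(write_foldx_text(foldx_runs))
            (pdir / "rosetta.out").write_text(write_rosetta_text(rosetta))

    ann_path = out_dir / "annotations.csv"
    pd.DataFrame.from_records(ann_records).to_csv(ann_path, index=False)

    # docking fixture pair for the screening path (not part of the matrix)
    ligands = {f"ZINC{i:04d}": [float(np.round(v, 2)) for v in rng.uniform(-11, -5, size=4)]
               for i in range(10)}
    mut_ligands = {lig: [float(np.round(v + rng.normal(0, 0.8), 2)) for v in poses]
                   for lig, poses in ligands.items()}
    wt_dock = out_dir / "wt_docking.txt"
    mut_dock = out_dir / "mut_docking.txt"
    wt_dock.write_text(write_docking_text(ligands))
    mut_dock.write_text(write_docking_text(mut_ligands))

    expected = LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.asarray(labels),
        groups=groups,
        feature_names=list(SEQ_FEATURES if config.mode == "SEQ" else STR_FEATURES),
        mode=config.mode,
    )
    return FixtureBundle(
        root=out_dir,
        annotations=ann_path,
        expected=expected,
        wt_docking=wt_dock,
        mut_docking=mut_dock,
        msa_paths=msa_paths,
    )
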