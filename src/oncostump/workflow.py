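"""High-level orchestration: featurize a bundle, run the training protocol,
predict, and rank screening deltas.  The CLI is a thin shell over these
functions; they are equally usable from Python.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boosting import StumpBoostingClassifier, render_prediction
from .conservation import compute_profile
from .errors import ModeError, SchemaError
from .evaluation import (
    average_precision,
    bootstrap_metric,
    grouped_split,
    model_selection,
    roc_auc,
)
from .features import AnnotationBundle, VariantSpec, assemble_features, ligand_deltas
from .io import (
    LabeledDataset,
    load_labeled_dataset,
    parse_docking_scores,
    parse_foldx_ddg,
    parse_p2rank_pockets,
    parse_propka,
    parse_rosetta_ddg,
    read_msa,
    save_model,
)
from .constants import SEQ_FEATURES, STR_FEATURES

logger = logging.getLogger(__name__)

# Default hyperparameter search space for the stump ensemble; brackets the
# 9-round (SEQ) and 15-round (STR) shapes of the final predictors.
DEFAULT_GRID = {
    "n_rounds": [5, 9, 15, 25, 50],
    "eta": [0.1, 0.3, 0.5],
    "lambda_": [0.5, 1.0, 2.0],
    "gamma_": [0.0, 0.1],
}

# Compact grid for repeated-seed robustness studies.
COMPACT_GRID = {
    "n_rounds": [5, 9, 15],
    "eta": [0.1, 0.3],
    "lambda_": [1.0],
    "gamma_": [0.0],
}

_LABEL_TO_INT = {"oncogenic": 1, "benign": 0, "1": 1, "0": 0}


def featurize_bundle(root, mode: str) -> LabeledDataset:
    """Run the raw-input bundle through parsers, conservation and assembly.

    Expected layout under ``root``: ``annotations.csv`` with columns
    protein, position, wt_aa, mut_aa, domain, predictsnp, essential_residues
    (space-separated positions) and optionally label; one sub-directory per
    protein with ``msa.fasta`` and, for STR mode, ``foldx.txt``,
    ``rosetta.out``, ``pockets.csv``, ``wt.propka`` and one
    ``<mutation>.propka`` per variant.
    """
    root = Path(root)
    ann = pd.read_csv(root / "annotations.csv", float_precision="round_trip")
    required = {"protein", "position", "wt_aa", "mut_aa", "domain",
                "predictsnp", "essential_residues"}
    missing = required - set(ann.columns)
    if missing:
        raise SchemaError(f"annotation table lacks column(s): {sorted(missing)}")

    profiles: dict[str, object] = {}
    per_protein: dict[str, dict] = {}
    rows, labels, groups = [], [], []
    for rec in ann.to_dict("records"):
        protein = str(rec["protein"])
        pdir = root / protein
        if protein not in profiles:
            profiles[protein] = compute_profile(read_msa(pdir / "msa.fasta"))
            info = {}
            if mode == "STR":
                for fname, key, parser in [
                    ("foldx.txt", "foldx", parse_foldx_ddg),
                    ("rosetta.out", "rosetta", parse_rosetta_ddg),
                    ("pockets.csv", "pockets", parse_p2rank_pockets),
                    ("wt.propka", "wt_pka", parse_propka),
                ]:
                    path = pdir / fname
                    if not path.exists():
                        raise ModeError(f"STR mode requires {fname} for protein {protein}")
                    info[key] = parser(path.read_text())
            per_protein[protein] = info

        variant = VariantSpec(protein, int(rec["position"]),
                              str(rec["wt_aa"]), str(rec["mut_aa"]))
        essential = {int(x) for x in str(rec["essential_residues"]).split()}
        kwargs = {}
        if mode == "STR":
            info = per_protein[protein]
            code = variant.code
            if code not in info["foldx"]:
                raise ModeError(f"no FoldX ddG for mutation {code}")
            if code not in info["rosetta"]:
                raise ModeError(f"no Rosetta ddG for mutation {code}")
            mut_propka = pdir / f"{code}.propka"
            if not mut_propka.exists():
                raise ModeError(f"missing mutant PROPKA output for {code}")
            kwargs = dict(
                foldx_ddg=info["foldx"][code],
                rosetta_ddg=info["rosetta"][code],
                pocket_residues=info["pockets"],
                wt_pka=info["wt_pka"],
                mut_pka=parse_propka(mut_propka.read_text()),
            )
        bundle = AnnotationBundle(
            essential_residues=essential,
            domain_label=str(rec["domain"]),
            predictsnp_score=float(rec["predictsnp"]),
            **kwargs,
        )
        fv = assemble_features(variant, bundle, profiles[protein], mode)
        rows.append(fv.values)
        groups.append((protein, variant.position))
        raw_label = str(rec.get("label", "0")).strip().lower()
        if raw_label not in _LABEL_TO_INT:
            raise SchemaError(f"non-binary label value {rec.get('label')!r}")
        labels.append(_LABEL_TO_INT[raw_label])

    return LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.asarray(labels),
        groups=groups,
        feature_names=list(SEQ_FEATURES if mode == "SEQ" else STR_FEATURES),
        mode=mode,
    )


def run_training_protocol(
    dataset: LabeledDataset,
    seed: int = 0,
    grid: dict | None = None,
    test_frac: float = 0.2,
    n_boot: int = 1000,
    k: int = 5,
):
    """Grouped 80/20 split, grouped 5-fold CV selection, final fit, held-out
    metrics with bootstrap summaries.

    Returns (model, report dict).
    """
    grid = grid or DEFAULT_GRID
    split = grouped_split(dataset.groups, test_frac=test_frac, seed=seed)
    X, y = dataset.matrix, dataset.labels
    tr, te = split.train_idx, split.test_idx
    groups_tr = [dataset.groups[i] for i in tr]
    best_params, cv_table = model_selection(X[tr], y[tr], groups_tr, grid, k=k, seed=seed)
    model = StumpBoostingClassifier(**best_params).fit(X[tr], y[tr])
    scores = model.predict_proba(X[te])[:, 1]
    auc_summary = bootstrap_metric(y[te], scores, "roc_auc", n_boot=n_boot, seed=seed)
    ap_summary = bootstrap_metric(y[te], scores, "average_precision", n_boot=n_boot, seed=seed)
    report = {
        "mode": dataset.mode,
        "seed": seed,
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "best_params": best_params,
        "n_stumps": len(model.stumps_),
        "test_roc_auc": auc_summary.point_estimate,
        "test_roc_auc_bootstrap_mean": auc_summary.bootstrap_mean,
        "test_roc_auc_bootstrap_sd": auc_summary.bootstrap_sd,
        "test_avg_precision": ap_summary.point_estimate,
        "test_avg_precision_bootstrap_mean": ap_summary.bootstrap_mean,
        "test_avg_precision_bootstrap_sd": ap_summary.bootstrap_sd,
        "cv_table": cv_table.to_dict("records"),
    }
    return model, report


def run_pipeline_once(
    dataset: LabeledDataset,
    seed: int,
    grid: dict | None = None,
    params: dict | None = None,
    test_frac: float = 0.2,
    k: int = 5,
) -> dict:
    """One split -> (optional CV selection) -> train -> held-out metrics.

    With ``params`` given the CV selection step is skipped; otherwise
    ``grid`` (default: the compact grid) is searched.  Used for the
    repeated-seed robustness and power studies.
    """
    split = grouped_split(dataset.groups, test_frac=test_frac, seed=seed)
    X, y = dataset.matrix, dataset.labels
    tr, te = split.train_idx, split.test_idx
    if params is None:
        groups_tr = [dataset.groups[i] for i in tr]
        params, _ = model_selection(X[tr], y[tr], groups_tr,
                                    grid or COMPACT_GRID, k=k, seed=seed)
    model = StumpBoostingClassifier(**params).fit(X[tr], y[tr])
    scores = model.predict_proba(X[te])[:, 1]
    return {
        "roc_auc": roc_auc(y[te], scores),
        "average_precision": average_precision(y[te], scores),
        "n_stumps": len(model.stumps_),
    }


def predict_table(model: StumpBoostingClassifier, X) -> pd.DataFrame:
    """Per-row oncogenicity call, confidence and top contributing stump."""
    X = np.asarray(X, dtype=float)
    probs = model.predict_proba(X)[:, 1]
    records = []
    for i, p in enumerate(probs):
        contribs = [
            (abs(model.eta * s.contributions(X[i:i + 1])[0]), j)
            for j, s in enumerate(model.stumps_)
        ]
        top = max(contribs)[1] if contribs else -1
        records.append(
            {
                "row": i,
                "probability_oncogenic": float(p),
                "call": render_prediction(float(p)),
                "top_stump": top,
                "top_stump_feature": (
                    model.stumps_[top].feature_index if top >= 0 else -1
                ),
            }
        )
    return pd.DataFrame.from_records(records)


def screen_delta_table(wt_path, mut_path) -> pd.DataFrame:
    """Ranked mutant-vs-wild-type binding-energy deltas from docking files."""
    wt = parse_docking_scores(Path(wt_path).read_text())
    mut = parse_docking_scores(Path(mut_path).read_text())
    deltas, unmatched = ligand_deltas(wt, mut)
    if unmatched:
        logger.warning("ligands present in only one input: %s", unmatched)
    return pd.DataFrame(
        {
            "rank": range(1, len(deltas) + 1),
            "ligand": [d.ligand_id for d in deltas],
            "e_wt": [d.e_wt for d in deltas],
            "e_mut": [d.e_mut for d in deltas],
            "delta": [d.delta for d in deltas],
        }
    )


def provenance_header(seed: int | None, config: dict | None = None) -> str:
    """Comment header stamped on TSV outputs; stable for fixed inputs."""
    blob = json.dumps(config or {}, sort_keys=True).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    return f"# oncostump {__version__} seed={seed} config_hash={digest}\n"


def save_trained(model, report, out_dir, dataset: LabeledDataset, seed: int):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model_path = out_dir / "model.json"
    save_model(model, model_path, mode=dataset.mode,
               feature_names=dataset.feature_names, seed=seed)
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return model_path
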