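# Methods

This note documents the models, numerical choices and known limitations of
the toolkit, in the spirit of a methods appendix.

## Conservation scoring

Each alignment column is summarised by a pseudocounted residue distribution
over the 20 canonical amino acids,

    p_a = (count_a + ε) / (n_nongap + 20 ε),      ε = 1e-6 by default,

where gaps contribute to a separate gap fraction and `X` (unknown residue)
is excluded from both the counts and the normaliser. An all-gap column falls
back to the background distribution and is flagged rather than rejected.

The column score is the Jensen–Shannon divergence (base-2 logs, so values
lie in [0, 1]) between the column distribution and a background *q*. The
shipped default background is the BLOSUM62 amino-acid frequency vector; a
uniform background is available. Raw scores are multiplied by
(1 − gap fraction), then blended with a windowed mean: with window weight
*w* = 0.5 and an odd window of 3 columns (truncated at the alignment ends),

    score_c = (1 − w)·raw_c + w·mean(raw over window around c),

clipped to [0, 1]. Window 3, weight 0.5 and ε = 1e-6 follow the published
defaults of the window-smoothed JSD conservation estimator this module
implements; all are configurable.

**Grading.** Scores are rank-binned into nine equal-frequency grades
(grade 1 = least conserved, 9 = most conserved); tied scores receive the
grade of their mean rank, so a flat profile collapses onto grade 5. The
companion mutability grade is 10 − conservation grade. Equal-frequency
binning is a documented stand-in: the grading thresholds of the upstream
web tools are not published, and any strictly monotone transform of the
scores leaves the grades unchanged, which the tests assert.

**Homolog filtering** retains sequences with > 50 % identity to the query
(computed over columns where both sequences are non-gap) and a non-gap
length within ± 20 % of the query's. It operates on an already-aligned set;
homolog retrieval and alignment construction are upstream concerns.

## Feature encoding

SEQ vectors have 9 columns, STR vectors 15; the exact orders are in
`oncostump.constants`. Conventions that matter:

* The consensus deleteriousness score is stored exactly as given, a signed
  confidence in [−1, +1] with positive = deleterious; the toolkit never
  rescales an upstream predictor's output.
* The pKa change of essential residues is expanded into three summary
  columns — largest rise, largest drop, and mean absolute change of
  pKa_mut − pKa_wt over essential positions ionisable in both structures.
  A single scalar would discard the direction information; three summaries
  keep the vector width fixed while remaining order-free. When no essential
  residue is ionisable in both structures all three are zero (logged, not
  an error).
* Structural features are never imputed. A 15-column request against a
  bundle missing any structural annotation is a hard `ModeError`; this
  mirrors maintaining two datasets (sequence-only and structure-annotated)
  rather than mixing imputed rows into the structural partition.
* FoldX stability scans list one value per run; the parser returns the
  arithmetic mean, computed over the sorted run values so the result is
  bit-identical under any row order.
* Docking results keep the best (minimum) energy per ligand;
  `ligand_deltas` ranks shared ligands by mutant-minus-wild-type energy
  ascending (ties broken by ligand id) and reports unmatched ligands
  separately instead of dropping them.

All residue positions are 1-based UniProt numbering; any renumbering between
structure and sequence coordinates is assumed to have happened upstream.

## Classifier

`StumpBoostingClassifier` is second-order (Newton) gradient boosting on the
logistic loss restricted to depth-1 trees, with L2 leaf regularisation λ,
split penalty γ and learning rate η. The base score is the log-odds of the
training class frequency. Split search is exact and exhaustive: thresholds
are midpoints between consecutive distinct sorted values, constant features
are skipped, and a round that finds no strictly positive gain stops boosting
early. Determinism is total: ties in the split search break to the lowest
feature index, then the lowest threshold, and training rows are internally
sorted into a canonical order so that row permutation changes nothing, not
even floating-point summation order. The test suite verifies margin-level
agreement (≤ 1e-6) with an independent exact-greedy reference
implementation configured identically.

Default hyperparameter search space: rounds {5, 9, 15, 25, 50},
η {0.1, 0.3, 0.5}, λ {0.5, 1, 2}, γ {0, 0.1} — wide enough to bracket the
9-stump (sequence) and 15-stump (structure) shapes the final predictors
take. Selection is by mean ROC AUC over grouped 5-fold cross-validation;
ties prefer fewer rounds, then smaller η. A compact grid
(rounds {5, 9, 15} × η {0.1, 0.3}) is used for repeated-seed studies where
the full grid would dominate runtime.

Reported confidence is round(100·max(p, 1−p)) % (half-up with a 1e-9 guard
so decimal boundaries such as p = 0.995 round to 100 %); the decision rule
calls a variant oncogenic at p > 0.5 and neutral at exactly 0.5, the
conservative choice for clinical-style reporting.

Baselines: a greedy Gini decision tree (exhaustive thresholds, leaves emit
class frequencies) and single-feature score baselines used directly as
rankers with a declared orientation.

## Evaluation protocol

* `grouped_split` shuffles (protein, position) groups with a seeded
  generator and accumulates whole groups into the test side until it holds
  20 % of rows (so the achieved fraction is within one group of the
  target). Splitting by protein only is available for cross-protein
  generalisation studies.
* `grouped_kfold` assigns groups largest-first to the currently smallest
  fold; fold sizes are never less balanced than round-robin assignment.
* ROC points sweep distinct score thresholds (ties grouped into one step);
  AUC is the trapezoid area, which equals the Mann–Whitney pairwise
  concordance statistic — asserted to 1e-12 in tests. Average precision is
  the step sum Σ (R_n − R_{n−1}) P_n; the PR curve is padded at recall 0
  with the precision of the highest threshold, and ROC curves with (0,0)
  and (1,1), so fixed-grid interpolation is defined at the ends.
* Bootstrap summaries resample rows with replacement (N = 1000);
  single-class resamples are redrawn and counted, keeping exactly N usable
  resamples. The standard deviation uses ddof = 1.
* Curve aggregation interpolates each curve onto 30 evenly spaced grid
  points in [0, 1] and reports pointwise 10 %/50 %/90 % quantiles with the
  linear-interpolation ("type 7") quantile rule.

## Synthetic data

The generator emulates the curated training data's structure: SEQ defaults
to 509 oncogenic / 564 benign rows, STR to 377 / 76 (the structural
partition is deliberately imbalanced to exercise imbalance handling), spread
over 44 proteins with positions drawn with replacement so that some
(protein, position) keys carry several mutations — the situation grouped
splitting exists for.

Continuous features are Gaussians (clipped to their valid ranges;
discretised for grades) whose oncogenic-class mean is shifted by
`effect_size × multiplier × sd` in the deleterious direction. The consensus
deleteriousness score and the conservation features get the largest
standardised shifts (multipliers 1.0 and 0.9), the stability scores smaller
ones (0.6), echoing the relative feature importances of the real predictor.
Binary features are Bernoulli with class-dependent rates — essentiality
0.6/0.1 and pocket membership 0.5/0.2 (oncogenic/benign) at the reference
effect size 2 — with the rate gap scaled linearly in `effect_size`, so
`effect_size = 0` yields exactly exchangeable classes and chance-level
classifiers. `label_noise` (default 0.05) makes a row draw its features
from the opposite class while keeping its label: mislabeled examples, with
class counts exactly as configured.

What the generator does **not** emulate: correlated features (real
conservation, stability and deleteriousness scores co-vary), per-position
feature sharing across mutations at the same site, realistic protein
lengths, or any actual physics in the ΔΔG/pKa/docking numbers. Passing the
recovery study therefore shows the pipeline recovers a known class signal
under grouped evaluation — not that real-data accuracy is reproduced.

`generate_raw_fixtures` writes alignment FASTA files and tool-output texts
together with the feature matrix they must reproduce; the identity of the
parse → conserve → featurize path with the generator's matrix is asserted
bit-exactly. Table round trips stay bit-exact because floats are written
with `%.17g` and read back with correctly rounded parsing.

## Problem sizes in the verification scripts

The repeated-seed studies use 50 seeds each: signal recovery at the SEQ
class sizes with compact-grid CV selection, and the null check
(effect size 0) with fixed 9-round parameters. Metric-oracle equivalence
uses 500 random instances of up to 200 rows; boosting parity 40 datasets of
50 rows; split hygiene 1000 random group structures. These sizes give
stable pass/fail behaviour while keeping the full verification run in the
tens of seconds.

## Known limitations

* The toolkit never runs FoldX, Rosetta, PROPKA, P2Rank, docking or
  alignment software; it parses one documented minimal dialect per tool,
  and real-world outputs may need light reformatting.
* The conservation grading is equal-frequency by construction and will not
  match web-server grades computed with unpublished fixed thresholds.
* Boosting is restricted to depth-1 trees with no row/column subsampling or
  monotonicity constraints; probabilities are raw sigmoids with no
  post-hoc calibration.
* Statistical model comparison (significance testing between classifiers)
  is out of scope; the evaluation module quantifies uncertainty per model
  only.
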