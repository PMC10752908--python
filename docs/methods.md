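# Methods

## Problem and model

The package addresses binary bioactivity classification from structure
alone: given SMILES and an IC50 (nM) against one protein target, predict
whether a new compound is an inhibitor. The model is a two-layer stacked
generalization. The first layer is a matrix of heterogeneous base
classifiers — eight learning algorithms crossed with up to nine molecular
fingerprint families — each producing a probabilistic feature (PF): its
out-of-fold predicted probability of activity. The second layer is an
RBF-SVM meta-classifier trained on a selected subset of PF columns.
Stacking heterogeneous probabilistic outputs lets the meta-model exploit
complementary error structure across descriptor spaces that no single
(algorithm, fingerprint) cell captures.

## Curation

* **Labeling.** Active: IC50 ≤ 1,000 nM; inactive: IC50 ≥ 10,000 nM;
  strictly between: intermediate, excluded from modeling along with rows
  lacking a usable IC50. These cutoffs are the convention of the
  estrogen-receptor QSAR lineage this design follows; both are
  config-exposed. Boundary values land on the adjacent definite class
  (≤ / ≥), so the three intervals partition (0, ∞).
* **Standardization.** RDKit cleanup → largest organic fragment
  (salt/counter-ion stripping; a parent fragment with no carbon is
  rejected as inorganic) → canonical tautomer → canonical SMILES. The
  map is deterministic and idempotent; idempotence is property-tested.
* **Duplicates** (same canonical SMILES) collapse to one record carrying
  the **median** of the observed IC50s — robust to the heavy-tailed assay
  outliers typical of public bioactivity data; first-occurrence order and
  identity are kept.
* **Units.** IC50 columns in µM/mM/M/pM are converted to nM; rows with an
  unrecognized unit are dropped with a warning (or rejected, per config).
* **Split.** Per class, exactly ⌊0.8·n⌋ records go to training under a
  seeded permutation. The per-class floor rule reproduces the reference
  counts exactly: 1145/851 actives/inactives → 916+680 train, 229+171
  test; 736/471 → 588+376 / 148+95.

## Fingerprints

Nine families with fixed widths: AP2D/AP2DC 780, KR/KRC 4860, MACCS 166,
PubChem 881, FP4/FP4C 307, RDK5 2048; AP2DC/KRC/FP4C are counts, the rest
binary. MACCS and RDK5 are computed natively with RDKit — MACCS drops the
toolkit's unused key 0 to honor the 166-key standard; RDK5 is the hashed
path fingerprint with `maxPath=5`, 2048 bits, other hashing parameters at
toolkit defaults. The remaining families are defined by PaDEL-Descriptor's
SMARTS libraries; re-deriving thousands of SMARTS definitions is out of
scope, so those blocks are **imported** from PaDEL CSV files and validated
(width, {0,1} semantics for binary families, non-negative integers for
counts, row alignment by compound id). Count columns are left as raw
counts; any scaling is the learner's concern. Zero-variance columns are
kept at import (full registry width) and dropped per-fit only inside
distance-based learners (KNN, PLS), where constant columns distort
geometry.

## Base classifiers and tuning

Algorithm mapping follows the R caret conventions the design descends
from: GLM = binomial logistic regression, rpart/CART = a single decision
tree, PLS = PLS-DA on one-hot class indicators with probabilities via a
softmax over predicted class scores; RF, SVM (RBF), XGB, KNN and a
one-hidden-layer MLP as named. Default grids (all config-overridable):

| algorithm | grid | fixed |
|---|---|---|
| RF | features/split ∈ {½√p, √p, 2√p} | 500 trees |
| GLM | L2 strength ∈ {0, 0.01, 1} | |
| SVM | C ∈ {0.1, 1, 10}, γ ∈ {1/p, 10/p} | RBF |
| XGB | depth ∈ {3, 6}, η ∈ {0.1, 0.3} | 200 rounds |
| KNN | k ∈ {3, 5, 7, 9} | |
| PLS | components ∈ {2, 4, 8} | |
| CART | complexity ∈ {0.001, 0.01, 0.1} | |
| MLP | hidden size ∈ {5, 10, 20} | 1 hidden layer |

Each cell is tuned by stratified k-fold (default 10) cross-validated
**MCC** — the pipeline's headline metric — over the grid's cartesian
product in declared order, first argmax winning ties; the winner is refit
on all training rows. A singleton grid skips the search. SVM
probabilities come from Platt-style sigmoid calibration fitted on
internal training folds (`CalibratedClassifierCV(SVC(), ensemble=False)`).
All learners are seed-deterministic, including RF bootstraps, MLP
initialization and XGB (single-thread histogram method).

## PF generation and the meta-classifier

The training rows are partitioned by one shared stratified 10-fold plan.
For each base cell, the fold-k model is trained on the other nine folds
and predicts fold k; assembling the ten disjoint out-of-fold prediction
vectors yields one full-length PF column in which **no entry was produced
by a model that saw that row's label**. The alternative protocol — every
fold model predicts all rows and the ten outputs are averaged pointwise —
lets nine of ten predictors see each row's label and is kept only behind
`pf_mode="average"` for comparison; the default is the leak-free
concatenation, and a perturbation test asserts the exclusion directly.
Hyperparameters are tuned once per cell on the full training split and
reused across folds (`pf_tuning="shared"`, the caret-style protocol);
`"per_fold"` re-tunes inside every fold at ~k× the cost.

Selection is two-step: (1) a 500-tree random forest ranks PF columns by
Gini impurity-decrease importance (permutation importance via config),
ties broken by column order; (2) each top-m prefix over an arithmetic
grid (default m = 5, 10, …, 70, i.e. 14 sizes against the full 72-column
matrix; clipped with a warning when the matrix is narrower) is scored by
an RBF-SVM (C=1, γ=scale) under one **shared** stratified fold plan — so
per-m differences reflect feature sets, not fold luck — and the highest
CV MCC wins, smaller m on ties (parsimony). The selected subset is always
a prefix of the ranking.

The meta-SVM is tuned over C ∈ {0.1, 1, 10, 100} × γ ∈ {1/d, 10/d}
(d = selected width) by shared-fold CV MCC, then refit with sigmoid
probability calibration. For new samples the PFs are the probabilities of
the base models refit on the entire training split — standard stacked
deployment; fold-averaging is the documented alternative.

## Evaluation

ACC, BACC = (Sn+Sp)/2 (an exact identity, asserted on every report), Sn,
Sp, MCC, and AUC as the tie-aware normalized Mann–Whitney statistic
(equal to exhaustive pair counting, property-tested). Cross-validation is
scored by **pooling** the out-of-fold predictions over one stratified plan
and computing each metric once (micro-averaging) — this matches the PF
construction and avoids undefined per-fold MCC on small folds; per-fold
macro-averaging is available via config. Degenerate MCC denominators
(an empty confusion marginal) map to 0 by convention. The classification
threshold is fixed at 0.5 throughout; no threshold tuning. Independent
test evaluation asserts id-disjointness from the training split before
scoring.

## Synthetic data

The generator emulates a raw ChEMBL-style table: molecules are built from
five ring templates (benzene, cyclohexane, cyclopentane, pyridine,
biphenyl) decorated with a head substituent, a short alkyl linker (0–3
carbons) and a branch substituent. Actives preferentially carry *motif*
heads — trifluoromethyl and N,N-dimethylamino, substructure classes
repeatedly implicated in estrogen-receptor inhibitor chemistry — while
neutral decorations (alkyl, alkoxy, halogen, nitrile, acyl, …) carry no
class information. IC50s are drawn uniformly inside the class ranges
(actives U(10, 900) nM, inactives U(12000, 90000) nM — safely inside the
labeling thresholds); label noise flips a molecule's IC50 range relative
to its structural class. Salt forms, duplicate measurements and invalid
SMILES are injected at configurable rates and must be repaired or
rejected by curation (round-trip tested). PaDEL-style files for imported
families plant a configurable fraction of label-correlated columns
(binary: bit = label flipped with probability (1−ρ)/2, so φ ≈ ρ; counts:
label-shifted Poisson rates); ρ = 0 yields a pure-noise family. All
outputs are byte-identical given the seed.

The decoration vocabulary is deliberately wide so that distinct molecules
remain distinguishable at fingerprint resolution: an earlier, narrower
vocabulary produced many linker-length-only variants that collapse to
identical MACCS rows, and chance label imbalance inside such twin groups
made memorizing learners' CV MCC drift to ±0.2 under zero signal. What
the generator does **not** emulate: real scaffold diversity, assay noise
models, activity cliffs, or class imbalance beyond the configured counts —
so passing tests demonstrate protocol correctness and recoverability of
planted signal, not real-world screening performance.

## Reference experiments

`stackqsar.benchmarks` fixes two desk-scale fixtures (600 compounds,
label noise 0.1, 3 families × 4 algorithms — MACCS native, FP4 import
with ρ = 0.6, PubChem import with ρ = 0; RF/GLM/KNN/CART with single-point
grids sized for a ten-seed single-CPU run; selection grid (2, 12, 2),
proportioned to the 12 PF columns). On the planted-motif fixture, a run
is scored as *recovered* when every selected PF column derives from a
signal-bearing family. On the ten frozen seeds: 9/10 recovered; the
stacked CV MCC is never more than 0.009 below the best base classifier;
the independent-test MCC stays within 0.05 of the CV MCC.

On the null fixture (motifs attached independently of class, ρ = 0
everywhere) the base CV MCC estimates center on ~0.004 with a maximum
|MCC| of 0.18 across 120 estimates, and the meta estimate reaches 0.20 on
one seed. Two effects set this scale, both verified by permutation
analysis rather than leakage: with 307–881 independent noise columns at
n ≈ 480 the expected maximum chance column–label correlation is ≈ 0.15,
and a decision tree converts such a column into a CV MCC of similar size;
and the meta estimate additionally carries the selection-optimism bias
inherent to cross-validating a meta-model on PF columns generated from
the same labels. The null suite therefore flags any systematic leakage
(which would appear as MCC ≫ 0.2) while honest zero-signal runs may
still graze ±0.2 in the extreme order statistic.

## Numerical and degenerate-input choices

* Ties in grid tuning → first candidate in declared enumeration order;
  ties in importance → column order; ties in subset size → smaller m.
* KNN's k is clipped to n−1; PLS components to min(p, n−1); a fold whose
  training part lost a class borrows one row of the other class (logged).
* An all-constant feature block fits with a warning rather than erroring.
* PF entries are validated to [0, 1]; binary blocks to {0, 1}; CSV
  round-trips use full float precision.
* Seeds derived from a master seed stay below 2³¹ for portability.

## Limitations

Exact reproduction of published per-target performance requires the
original curated datasets and the original PaDEL fingerprint matrices;
this package reproduces the method and its protocol-level behavior, with
external fingerprint families entering via validated import. The
supplementary hyperparameter grids of the original study are not public;
the defaults above are this package's own documented choices. No
applicability-domain analysis, SHAP interpretation, or regression-mode
(pIC50) modeling.
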