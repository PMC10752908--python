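"""Reference synthetic experiments used to validate the stacked pipeline.

Two standard fixtures, sized for a single CPU:

* **planted-motif fixture** — 600 compounds (300 active / 300 inactive),
  label noise 0.1, three fingerprint families × four algorithms. Signal
  lives in two families: MACCS keys respond to the planted motif chemistry
  (trifluoromethyl / tertiary-amine decorations on actives) and the
  imported substructure family carries label-correlated columns (phi ≈
  0.6); the imported PubChem family is pure noise. Ground truth: the
  informative PF columns are exactly those derived from the two signal
  families.
* **null fixture** — same shape, but motifs are attached independently of
  class and all imported columns are uncorrelated, so every honest CV MCC
  estimate must sit near zero.

Each experiment runs the full pipeline (generate → curate → split →
featurize → stack → select → evaluate) from a single seed.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .curation import curate, read_compound_table, stratified_split
from .descriptors import build_blocks
from .metrics import evaluate_independent
from .selection import SelectionGrid
from .stacking import StackedEnsembleClassifier, fit_stacker
from .synthetic import SyntheticSpec, gen_imported_fp_files, gen_labeled_smiles

FIXTURE_ALGORITHMS: Sequence[str] = ("RF", "GLM", "KNN", "CART")
FIXTURE_DESCRIPTORS: Sequence[str] = ("MACCS", "FP4", "Pubchem")
#: Families whose PF columns carry real signal in the planted-motif fixture.
INFORMATIVE_FAMILIES: Sequence[str] = ("MACCS", "FP4")
#: Per-family planted column/label correlation for the imported files.
FIXTURE_CORRELATIONS: Mapping[str, float] = {"FP4": 0.6, "Pubchem": 0.0}

#: Single-point grids keep the fixture runs cheap; tuning behaviour itself is
#: exercised by the unit tests with multi-point grids.
FIXTURE_GRIDS: Mapping[str, Mapping[str, list]] = {
    "RF": {"max_features_mult": [1.0], "n_estimators": [150]},
    "GLM": {"l2": [0.01]},
    "KNN": {"n_neighbors": [5]},
    "CART": {"ccp_alpha": [0.01]},
}

#: Subset-size grid proportioned to the fixture's 12 PF columns.
FIXTURE_SELECTION_GRID = SelectionGrid(2, 12, 2)


def motif_spec(seed: int, null: bool = False) -> SyntheticSpec:
    """The fixture's generator conditions (600 compounds, noise 0.1)."""
    return SyntheticSpec(
        n_active=300,
        n_inactive=300,
        label_noise=0.1,
        motif_active_prob=0.5 if null else 1.0,
        motif_inactive_prob=0.5 if null else 0.0,
        seed=seed,
    )


@dataclass
class FixtureRunResult:
    seed: int
    selected_columns: list[str]
    recovered: bool
    base_cv_mcc: dict[str, float]
    best_base_cv_mcc: float
    meta_cv_mcc: float
    independent_mcc: float

    @property
    def max_abs_cv_mcc(self) -> float:
        return max(
            max(abs(v) for v in self.base_cv_mcc.values()), abs(self.meta_cv_mcc)
        )


def _featurize(spec: SyntheticSpec, dataset, out_dir: Path, correlations) -> dict:
    blocks = build_blocks(dataset.records, ["MACCS"])
    imported = [d for d in FIXTURE_DESCRIPTORS if d != "MACCS"]
    paths = gen_imported_fp_files(spec, dataset, imported, out_dir, correlations=correlations)
    blocks.update(build_blocks(dataset.records, imported, paths))
    return blocks


def run_fixture(seed: int, null: bool = False, work_dir: str | Path | None = None) -> FixtureRunResult:
    """Full pipeline on the planted-motif (or null) fixture for one seed."""
    spec = motif_spec(seed, null=null)
    correlations = dict(FIXTURE_CORRELATIONS)
    if null:
        correlations = {k: 0.0 for k in correlations}
    with tempfile.TemporaryDirectory() as tmp:
        work = Path(work_dir) if work_dir is not None else Path(tmp)
        table = work / f"table_{seed}.csv"
        gen_labeled_smiles(spec).to_csv(table, index=False)
        dataset = curate(read_compound_table(table))
        train, test = stratified_split(dataset, 0.8, seed=seed)
        blocks = _featurize(spec, train, work / "fp_train", correlations)
        model = fit_stacker(
            train,
            blocks,
            algorithms=FIXTURE_ALGORITHMS,
            grids=FIXTURE_GRIDS,
            k=10,
            selection_grid=FIXTURE_SELECTION_GRID,
            random_state=seed,
        )
        test_blocks = _featurize(spec, test, work / "fp_test", correlations)
        indep = evaluate_independent(model, test, test_blocks)

    base_cv = {name: rep.MCC for name, rep in model.base_cv_reports_.items()}
    informative = {
        name for name in model.pf_matrix_.column_names
        if name.split("__")[1] in INFORMATIVE_FAMILIES
    }
    recovered = bool(model.selected_columns_) and set(model.selected_columns_) <= informative
    return FixtureRunResult(
        seed=seed,
        selected_columns=list(model.selected_columns_),
        recovered=recovered,
        base_cv_mcc=base_cv,
        best_base_cv_mcc=max(base_cv.values()),
        meta_cv_mcc=model.cv_report(train.y).MCC,
        independent_mcc=indep.MCC,
    )


def run_many(seeds: Sequence[int], null: bool = False) -> list[FixtureRunResult]:
    return [run_fixture(int(s), null=null) for s in seeds]


def fixture_seeds(base_seed: int, n: int = 10) -> list[int]:
    """n distinct derived seeds, kept below 2**31."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]
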