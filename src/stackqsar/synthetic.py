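"""Synthetic bioactivity fixtures with recoverable structure–activity signal.

Generates ChEMBL-like raw compound tables (SMILES + IC50 in nM) by
decorating simple scaffolds (benzene, cyclohexane, biphenyl) with
substituent fragments. Actives preferentially carry "motif" decorations —
by default a trifluoromethyl group and a tertiary amine, two substructure
classes repeatedly implicated in estrogen-receptor inhibitors — so that
substructure fingerprints contain a planted, recoverable signal. Label
noise, salt forms, duplicate measurements and invalid SMILES rows are
injected at configurable rates to exercise the curation pipeline.

PaDEL-style fingerprint CSV files for the non-native families are
fabricated with a configurable fraction of label-correlated columns, which
gives feature selection a known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import LabeledDataset
from .descriptors import registry_entry

# Scaffold templates with a head substituent {a} and a branch substituent {b}.
# Deliberately varied ring systems so that distinct molecules stay
# distinguishable at fingerprint resolution (linker-only variants collapse
# to identical MACCS rows and would correlate twin labels by chance).
_TEMPLATES = (
    "{a}c1ccc({b})cc1",
    "{a}C1CCC({b})CC1",
    "{a}c1ccc(-c2ccc({b})cc2)cc1",
    "{a}c1ccc({b})cn1",
    "{a}C1CCC({b})C1",
)

#: Default active-enriched decorations: trifluoromethyl and N,N-dimethylamino.
DEFAULT_MOTIFS = ("FC(F)(F)", "CN(C)C")

_NEUTRAL_HEADS = ("C", "CC", "CCC", "O", "CO", "Cl", "CC(=O)", "N#C", "OCC", "C(C)(C)C")
_BRANCHES = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC",
    "Cl", "Br", "I", "C=C", "C(=O)C", "C(=O)OC",
)
_LINKERS = tuple("C" * k for k in range(4))

_INVALID_SMILES = ("C1CC(", "X#Y!!", "c1ccccc", "C(C)(C)(C)(C)C1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic bioactivity table.

    IC50 ranges default to U(10, 900) nM for actives and U(12000, 90000) nM
    for inactives — safely inside the conventional 1 µM / 10 µM labeling
    thresholds. ``motif_active_prob`` / ``motif_inactive_prob`` control how
    strongly the motif decorations track the class (1/0 = deterministic
    signal; 0.5/0.5 = a structure-free null dataset).
    """

    n_active: int = 50
    n_inactive: int = 50
    motif_smarts: Sequence[str] = DEFAULT_MOTIFS
    label_noise: float = 0.0
    ic50_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (10.0, 900.0),
        (12000.0, 90000.0),
    )
    salt_rate: float = 0.0
    duplicate_rate: float = 0.0
    invalid_rate: float = 0.0
    motif_active_prob: float = 1.0
    motif_inactive_prob: float = 0.0
    fp_informative_fraction: float = 0.05
    fp_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        for rate in (self.salt_rate, self.duplicate_rate, self.invalid_rate):
            if not 0 <= rate < 1:
                raise ValueError("injection rates must lie in [0, 1)")
        (a_lo, a_hi), (i_lo, i_hi) = self.ic50_ranges
        if not (0 < a_lo < a_hi and 0 < i_lo < i_hi):
            raise ValueError("invalid ic50 ranges")


def _build_pool(heads: Sequence[str], rng: np.random.Generator, n: int,
                seen: set[str]) -> list[str]:
    """Sample n unique (by canonical SMILES) molecules built from templates."""
    combos = [
        (t, h, link, b)
        for t in _TEMPLATES
        for h in heads
        for link in _LINKERS
        for b in _BRANCHES
    ]
    rng.shuffle(combos)
    out: list[str] = []
    for t, h, link, b in combos:
        smiles = t.format(a=h + link, b=b)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # template artifact; skip
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(smiles)
        if len(out) == n:
            return out
    raise ValueError(
        f"cannot build {n} unique molecules from the scaffold pool (got {len(out)})"
    )


def gen_labeled_smiles(spec: SyntheticSpec) -> pd.DataFrame:
    """A raw compound table (columns id, smiles, ic50_nM), seed-deterministic.

    Molecules are unique by canonical structure before injection; label
    noise flips the IC50 range of a molecule relative to its structural
    class; salts append a counter-ion fragment; duplicates re-measure an
    existing structure with a fresh IC50 from the same class range; invalid
    rows carry unparseable SMILES.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()

    n = spec.n_active + spec.n_inactive
    # motif presence is structural; the class decides how likely it is
    motif_flags = np.concatenate([
        rng.random(spec.n_active) < spec.motif_active_prob,
        rng.random(spec.n_inactive) < spec.motif_inactive_prob,
    ])
    classes = np.array([1] * spec.n_active + [0] * spec.n_inactive)

    n_motif = int(motif_flags.sum())
    motif_pool = _build_pool(list(spec.motif_smarts), rng, n_motif, seen) if n_motif else []
    plain_pool = _build_pool(list(_NEUTRAL_HEADS), rng, n - n_motif, seen)
    mi = pi = 0
    smiles_list: list[str] = []
    for has_motif in motif_flags:
        if has_motif:
            smiles_list.append(motif_pool[mi]); mi += 1
        else:
            smiles_list.append(plain_pool[pi]); pi += 1

    # label noise: IC50 drawn from the other class's range
    flips = rng.random(n) < spec.label_noise
    labels = np.where(flips, 1 - classes, classes)
    (a_lo, a_hi), (i_lo, i_hi) = spec.ic50_ranges
    ic50 = np.where(
        labels == 1,
        rng.uniform(a_lo, a_hi, size=n),
        rng.uniform(i_lo, i_hi, size=n),
    )

    rows = [
        {"id": f"SYN{i:05d}", "smiles": s, "ic50_nM": float(v)}
        for i, (s, v) in enumerate(zip(smiles_list, ic50))
    ]

    # salts: counter-ion fragment appended (curation strips it)
    for i in np.flatnonzero(rng.random(n) < spec.salt_rate):
        rows[i] = {**rows[i], "smiles": rows[i]["smiles"] + ".Cl"}

    extra: list[dict] = []
    next_id = n
    for i in np.flatnonzero(rng.random(n) < spec.duplicate_rate):
        lo, hi = (a_lo, a_hi) if labels[i] == 1 else (i_lo, i_hi)
        extra.append({
            "id": f"SYN{next_id:05d}",
            "smiles": rows[i]["smiles"],
            "ic50_nM": float(rng.uniform(lo, hi)),
        })
        next_id += 1
    n_invalid = int(np.round(spec.invalid_rate * n))
    for j in range(n_invalid):
        extra.append({
            "id": f"SYN{next_id:05d}",
            "smiles": _INVALID_SMILES[j % len(_INVALID_SMILES)],
            "ic50_nM": float(rng.uniform(a_lo, i_hi)),
        })
        next_id += 1

    df = pd.DataFrame(rows + extra)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def gen_imported_fp_files(
    spec: SyntheticSpec,
    dataset: LabeledDataset,
    names: Sequence[str],
    out_dir: str | Path,
    correlations: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Fabricate PaDEL-dialect fingerprint CSVs for non-native families.

    A fraction ``spec.fp_informative_fraction`` of each file's columns is
    label-correlated (binary columns: bit = label flipped with probability
    (1−ρ)/2, giving phi ≈ ρ; count columns: Poisson rate shifted with the
    label); remaining columns are independent noise. Per-family correlation
    overrides come via ``correlations`` (0 ⇒ a pure-noise family).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    y = dataset.y
    ids = [r.id for r in dataset.records]
    paths: dict[str, Path] = {}
    for name in names:
        entry = registry_entry(name)
        rho = (correlations or {}).get(name, spec.fp_correlation)
        name_tag = zlib.crc32(name.encode()) % 7919
        rng = np.random.default_rng((spec.seed * 9176 + name_tag) % 2**31)
        width = entry.width
        n_info = int(round(spec.fp_informative_fraction * width)) if rho > 0 else 0
        mat = np.zeros((len(y), width), dtype=np.int64)
        if entry.value_kind == "binary":
            eps = (1.0 - rho) / 2.0
            for j in range(n_info):
                flip = rng.random(len(y)) < eps
                mat[:, j] = np.where(flip, 1 - y, y)
            p = rng.uniform(0.05, 0.5, size=width - n_info)
            mat[:, n_info:] = (rng.random((len(y), width - n_info)) < p).astype(np.int64)
        else:
            for j in range(n_info):
                mat[:, j] = rng.poisson(1.0 + 3.0 * rho * y)
            mat[:, n_info:] = rng.poisson(1.0, size=(len(y), width - n_info))
        cols = [f"{name}_{i}" for i in range(width)]
        df = pd.DataFrame(mat, columns=cols)
        df.insert(0, "Name", ids)
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
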