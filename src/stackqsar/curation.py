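"""Curation of raw SMILES / IC50 compound tables.

Turns a bioactivity export (generic CSV or a ChEMBL-style export) into a
labeled, deduplicated dataset ready for featurization: structures are
desalted, tautomer-standardized and canonicalized with RDKit, duplicate
structures are collapsed to the median IC50, activity labels are assigned
from IC50 thresholds, and the labeled records are split per class into
training and independent-test subsets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

Label = Literal["active", "inactive", "intermediate", "unlabeled"]
Split = Literal["train", "test", "none"]


class CurationError(ValueError):
    """Base class for curation failures."""


class ConfigurationError(CurationError):
    """Input table does not expose the mandatory columns."""


class SmilesParseError(CurationError):
    """A SMILES string could not be parsed."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}" + (f" ({detail})" if detail else ""))


class InorganicRejectionError(CurationError):
    """The desalted parent fragment contains no carbon."""


class StratificationError(CurationError):
    """A class required for stratification is empty."""


@dataclass(frozen=True)
class LabelThresholds:
    """IC50 cutoffs (nM) separating actives, intermediates and inactives.

    Compounds at or below ``active_max_nM`` are active; at or above
    ``inactive_min_nM`` inactive; strictly between the two, intermediate
    (discarded from modeling).
    """

    active_max_nM: float = 1000.0
    inactive_min_nM: float = 10000.0

    def __post_init__(self) -> None:
        if not (self.active_max_nM > 0 and self.inactive_min_nM > 0):
            raise ValueError("thresholds must be positive")
        if not self.active_max_nM < self.inactive_min_nM:
            raise ValueError("active_max_nM must be < inactive_min_nM")


@dataclass
class CompoundRecord:
    """One molecule: identifiers, structures, potency and activity label."""

    id: str
    smiles_raw: str
    smiles_canonical: str | None = None
    ic50_nM: float | None = None
    label: Label = "unlabeled"

    def __post_init__(self) -> None:
        if self.ic50_nM is not None:
            if not math.isfinite(self.ic50_nM) or self.ic50_nM <= 0:
                raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM}")


@dataclass
class LabeledDataset:
    """Ordered curated records plus a per-id train/test split assignment."""

    records: list[CompoundRecord]
    target_name: str = ""
    split: dict[str, Split] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        return LabeledDataset(
            records=recs,
            target_name=self.target_name,
            split={r.id: self.split.get(r.id, "none") for r in recs},
        )

    def labeled(self) -> "LabeledDataset":
        """Records usable for modeling (active or inactive only)."""
        return LabeledDataset(
            records=[r for r in self.records if r.label in ("active", "inactive")],
            target_name=self.target_name,
            split=dict(self.split),
        )

    @property
    def y(self) -> np.ndarray:
        """Binary labels for modeling records order: active=1, inactive=0."""
        return np.array(
            [1 if r.label == "active" else 0 for r in self.records], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles_canonical or r.smiles_raw for r in self.records],
                "ic50_nM": [r.ic50_nM for r in self.records],
                "label": [r.label for r in self.records],
                "split": [self.split.get(r.id, "none") for r in self.records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, target_name: str = "") -> "LabeledDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        records = []
        split: dict[str, Split] = {}
        for row in df.itertuples(index=False):
            ic50 = None if pd.isna(row.ic50_nM) else float(row.ic50_nM)
            records.append(
                CompoundRecord(
                    id=str(row.id),
                    smiles_raw=row.smiles,
                    smiles_canonical=row.smiles,
                    ic50_nM=ic50,
                    label=row.label,
                )
            )
            split[str(row.id)] = row.split
        return cls(records=records, target_name=target_name, split=split)


# Column-name resolution per input dialect. Matching is case-insensitive on
# the normalized (stripped) header.
_DIALECTS: Mapping[str, Mapping[str, Sequence[str]]] = {
    "generic_csv": {
        "id": ("id", "compound_id", "name", "molecule_id"),
        "smiles": ("smiles", "canonical_smiles"),
        "ic50": ("ic50_nm", "ic50", "standard_value"),
        "units": ("units", "unit", "standard_units"),
    },
    "chembl_export": {
        "id": ("molecule chembl id", "molecule_chembl_id", "chembl id"),
        "smiles": ("smiles", "canonical_smiles"),
        "ic50": ("standard value", "standard_value"),
        "units": ("standard units", "standard_units"),
    },
}

_UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,
    "mm": 1e6,
    "m": 1e9,
    "pm": 1e-3,
}


def _resolve_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {c.strip().lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_compound_table(
    path: str | Path,
    dialect: Literal["generic_csv", "chembl_export"] = "generic_csv",
    on_unknown_unit: Literal["drop", "error"] = "drop",
) -> list[CompoundRecord]:
    """Read a compound table into raw (unstandardized) records.

    IC50 values are converted to nM using the unit column when present
    (µM ×1000, M ×1e9, ...). Rows with unparseable or non-positive IC50
    keep ``ic50_nM=None`` (later labeled ``unlabeled``); rows with an
    unknown unit are dropped or rejected per ``on_unknown_unit``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise CurationError(f"empty compound table: {path}")
    spec = _DIALECTS[dialect]
    col_id = _resolve_column(df.columns, spec["id"])
    col_smiles = _resolve_column(df.columns, spec["smiles"])
    col_ic50 = _resolve_column(df.columns, spec["ic50"])
    col_units = _resolve_column(df.columns, spec["units"])
    missing = [
        name
        for name, col in (("id", col_id), ("smiles", col_smiles), ("ic50", col_ic50))
        if col is None
    ]
    if missing:
        raise ConfigurationError(
            f"table {path} lacks mandatory column(s) {missing} for dialect {dialect!r}"
        )

    records: list[CompoundRecord] = []
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        ic50: float | None
        try:
            ic50 = float(rowd[col_ic50])
        except (TypeError, ValueError):
            ic50 = None
        if ic50 is not None and not (math.isfinite(ic50) and ic50 > 0):
            ic50 = None
        if ic50 is not None and col_units is not None:
            unit = str(rowd[col_units]).strip().lower()
            if unit in ("", "nan", "none"):
                pass  # assume nM
            elif unit in _UNIT_TO_NM:
                ic50 *= _UNIT_TO_NM[unit]
            elif on_unknown_unit == "error":
                raise CurationError(f"unknown IC50 unit {unit!r} for id {rowd[col_id]!r}")
            else:
                logger.warning("dropping row %s: unknown IC50 unit %r", rowd[col_id], unit)
                continue
        records.append(
            CompoundRecord(id=str(rowd[col_id]), smiles_raw=str(rowd[col_smiles]), ic50_nM=ic50)
        )
    return records


_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()


def standardize_structure(smiles_raw: str) -> str:
    """Canonical, desalted, tautomer-standardized SMILES.

    Keeps the largest organic fragment (salt/counter-ion stripping),
    canonicalizes the tautomer, and returns the RDKit canonical SMILES.
    Deterministic and idempotent. Raises :class:`SmilesParseError` for
    unparseable input and :class:`InorganicRejectionError` when the parent
    fragment contains no carbon.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise SmilesParseError(smiles_raw)
    mol = rdMolStandardize.Cleanup(mol)
    mol = _FRAGMENT_CHOOSER.choose(mol)
    if not any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms()):
        raise InorganicRejectionError(
            f"no organic fragment after desalting: {smiles_raw!r}"
        )
    mol = _TAUTOMER_ENUMERATOR.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


def standardize_records(
    records: Iterable[CompoundRecord], on_error: Literal["drop", "raise"] = "drop"
) -> list[CompoundRecord]:
    """Apply :func:`standardize_structure` to every record.

    Invalid structures are dropped with a logged warning (default) or
    re-raised.
    """
    out: list[CompoundRecord] = []
    for rec in records:
        try:
            canonical = standardize_structure(rec.smiles_raw)
        except CurationError as exc:
            if on_error == "raise":
                raise
            logger.warning("dropping record %s: %s", rec.id, exc)
            continue
        out.append(replace(rec, smiles_canonical=canonical))
    return out


def deduplicate(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Collapse records sharing a canonical SMILES to one record.

    The retained IC50 is the median of the duplicates' observed IC50
    values (records with missing IC50 do not contribute); output order is
    first-occurrence order and identity of the first record's id.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = rec.smiles_canonical
        if key is None:
            raise ValueError(f"record {rec.id} is not standardized")
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out = []
    for key in order:
        members = groups[key]
        first = members[0]
        ic50s = [m.ic50_nM for m in members if m.ic50_nM is not None]
        ic50 = float(np.median(ic50s)) if ic50s else None
        out.append(replace(first, ic50_nM=ic50))
    return out


def assign_label(
    ic50_nM: float | None, thresholds: LabelThresholds = LabelThresholds()
) -> Label:
    """Map an IC50 (nM) to active / inactive / intermediate / unlabeled."""
    if ic50_nM is None:
        return "unlabeled"
    if ic50_nM <= 0 or not math.isfinite(ic50_nM):
        raise ValueError(f"ic50_nM must be positive, got {ic50_nM}")
    if ic50_nM <= thresholds.active_max_nM:
        return "active"
    if ic50_nM >= thresholds.inactive_min_nM:
        return "inactive"
    return "intermediate"


def label_records(
    records: Iterable[CompoundRecord], thresholds: LabelThresholds = LabelThresholds()
) -> list[CompoundRecord]:
    return [replace(r, label=assign_label(r.ic50_nM, thresholds)) for r in records]


def curate(
    records: Iterable[CompoundRecord],
    thresholds: LabelThresholds = LabelThresholds(),
    target_name: str = "",
    keep_intermediates: bool = False,
) -> LabeledDataset:
    """Full curation chain: standardize → deduplicate → label → dataset.

    Intermediate and unlabeled records are excluded from the modeling
    dataset unless ``keep_intermediates`` is set.
    """
    recs = label_records(deduplicate(standardize_records(records)), thresholds)
    if not keep_intermediates:
        recs = [r for r in recs if r.label in ("active", "inactive")]
    return LabeledDataset(records=recs, target_name=target_name)


def stratified_split(
    dataset: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per-class random split: exactly floor(fraction × class size) to train.

    Within each label class the records are permuted with a RNG seeded by
    ``seed`` and the first floor(fraction·n) go to the training split, the
    remainder to test. Deterministic given the seed.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError("train_fraction must lie in (0, 1]")
    labeled = [r for r in dataset.records if r.label in ("active", "inactive")]
    classes = {"active", "inactive"}
    by_class = {c: [r.id for r in labeled if r.label == c] for c in classes}
    for c, ids in by_class.items():
        if not ids:
            raise StratificationError(f"class {c!r} has no members")
    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    for c in sorted(by_class):
        ids = by_class[c]
        n_train = math.floor(train_fraction * len(ids))
        perm = rng.permutation(len(ids))
        train_ids.update(ids[i] for i in perm[:n_train])
    split: dict[str, Split] = {
        r.id: ("train" if r.id in train_ids else "test") for r in labeled
    }
    dataset.split.update(split)
    train = dataset.subset([r.id for r in labeled if split[r.id] == "train"])
    test = dataset.subset([r.id for r in labeled if split[r.id] == "test"])
    return train, test
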