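"""Fingerprint feature blocks.

Nine fingerprint families are supported as fixed-width blocks: MACCS keys
and the 2048-bit hashed path fingerprint (max path length 5, "RDK5") are
computed natively with RDKit; the PaDEL-defined families (2D atom pairs,
Klekota–Roth, PubChem and SMARTS substructure fingerprints, each in binary
and — where defined — count form) are accepted as precomputed matrices in
the PaDEL CSV dialect and validated against the registry before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .curation import CompoundRecord

NATIVE_FAMILIES = ("MACCS", "RDK5")


class RegistryError(KeyError):
    """Unknown fingerprint family."""


class BlockSchemaError(ValueError):
    """Imported block does not match the registry contract."""


class AlignmentError(ValueError):
    """Imported block rows cannot be aligned with the dataset records."""


@dataclass(frozen=True)
class DescriptorRegistryEntry:
    name: str
    width: int
    value_kind: Literal["binary", "count"]
    provenance: Literal["native", "imported"]


#: The nine supported fingerprint families and their fixed widths.
REGISTRY: Mapping[str, DescriptorRegistryEntry] = {
    e.name: e
    for e in (
        DescriptorRegistryEntry("AP2D", 780, "binary", "imported"),
        DescriptorRegistryEntry("AP2DC", 780, "count", "imported"),
        DescriptorRegistryEntry("KR", 4860, "binary", "imported"),
        DescriptorRegistryEntry("KRC", 4860, "count", "imported"),
        DescriptorRegistryEntry("MACCS", 166, "binary", "native"),
        DescriptorRegistryEntry("Pubchem", 881, "binary", "imported"),
        DescriptorRegistryEntry("FP4", 307, "binary", "imported"),
        DescriptorRegistryEntry("FP4C", 307, "count", "imported"),
        DescriptorRegistryEntry("RDK5", 2048, "binary", "native"),
    )
}


def registry_entry(name: str) -> DescriptorRegistryEntry:
    """Fixed width / value kind / provenance for a fingerprint family."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise RegistryError(
            f"unknown fingerprint family {name!r}; known: {sorted(REGISTRY)}"
        ) from None


@dataclass
class FingerprintBlock:
    """An n_compounds × width feature matrix for one fingerprint family."""

    name: str
    matrix: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        entry = registry_entry(self.name)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != entry.width:
            raise BlockSchemaError(
                f"{self.name}: expected width {entry.width}, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] != len(self.row_ids):
            raise AlignmentError(
                f"{self.name}: {self.matrix.shape[0]} rows vs {len(self.row_ids)} ids"
            )
        if self.matrix.size:
            if np.any(self.matrix < 0):
                raise ValueError(f"{self.name}: negative feature values")
            if entry.value_kind == "binary" and not np.isin(self.matrix, (0, 1)).all():
                raise ValueError(f"{self.name}: binary block contains values outside {{0,1}}")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write in the PaDEL CSV dialect (first column ``Name``)."""
        entry = registry_entry(self.name)
        cols = [f"{self.name}_{i}" for i in range(entry.width)]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "Name", self.row_ids)
        df.to_csv(path, index=False)


def compute_native(records: Sequence[CompoundRecord], name: str) -> FingerprintBlock:
    """Compute MACCS (166 keys; RDKit's unused bit 0 dropped) or the
    2048-bit max-path-5 hashed path fingerprint for standardized records."""
    entry = registry_entry(name)
    if name not in NATIVE_FAMILIES:
        raise RegistryError(f"{name!r} is not natively computable; import it instead")
    rows = np.zeros((len(records), entry.width), dtype=np.uint8)
    for i, rec in enumerate(records):
        smiles = rec.smiles_canonical or rec.smiles_raw
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # curation should have rejected this
            raise RuntimeError(f"internal error: unparseable SMILES {smiles!r} (id {rec.id})")
        if name == "MACCS":
            fp = rdMolDescriptors.GetMACCSKeysFingerprint(mol)  # 167 bits, bit 0 unused
            bits = np.zeros(167, dtype=np.uint8)
            bits[list(fp.GetOnBits())] = 1
            rows[i] = bits[1:]
        else:  # RDK5
            fp = Chem.RDKFingerprint(mol, maxPath=5, fpSize=entry.width)
            on = np.zeros(entry.width, dtype=np.uint8)
            on[list(fp.GetOnBits())] = 1
            rows[i] = on
    return FingerprintBlock(name=name, matrix=rows, row_ids=[r.id for r in records])


def import_block(
    path: str | Path, name: str, records: Sequence[CompoundRecord]
) -> FingerprintBlock:
    """Load a precomputed fingerprint matrix (PaDEL CSV dialect).

    The first column must be ``Name`` (compound ids); rows are reordered to
    match ``records`` order. Width, binary {0,1} semantics and count
    non-negativity are validated against the registry.
    """
    entry = registry_entry(name)
    df = pd.read_csv(path)
    if df.columns[0] != "Name":
        raise BlockSchemaError(f"{path}: first column must be 'Name', got {df.columns[0]!r}")
    n_features = df.shape[1] - 1
    if n_features != entry.width:
        raise BlockSchemaError(
            f"{name}: expected {entry.width} feature columns, found {n_features} in {path}"
        )
    df = df.set_index(df["Name"].astype(str)).drop(columns="Name")
    missing = [r.id for r in records if r.id not in df.index]
    if missing:
        raise AlignmentError(f"{name}: ids missing from {path}: {missing[:5]}...")
    matrix = df.loc[[r.id for r in records]].to_numpy(dtype=float)
    if entry.value_kind == "count":
        if np.any(matrix < 0):
            raise ValueError(f"{name}: negative counts in {path}")
        if not np.allclose(matrix, np.round(matrix)):
            raise ValueError(f"{name}: non-integer counts in {path}")
        matrix = matrix.astype(np.int64)
    return FingerprintBlock(name=name, matrix=matrix, row_ids=[r.id for r in records])


def available_descriptors(import_paths: Mapping[str, str | Path] | None = None) -> list[str]:
    """Families usable in a run: the native two plus configured imports.

    Order follows the registry enumeration (stable across runs).
    """
    import_paths = import_paths or {}
    for name in import_paths:
        registry_entry(name)
    enabled = set(NATIVE_FAMILIES) | set(import_paths)
    return [name for name in REGISTRY if name in enabled]


def build_blocks(
    records: Sequence[CompoundRecord],
    names: Iterable[str],
    import_paths: Mapping[str, str | Path] | None = None,
) -> dict[str, FingerprintBlock]:
    """Materialize the requested blocks, native or imported, row-aligned."""
    import_paths = import_paths or {}
    blocks: dict[str, FingerprintBlock] = {}
    for name in names:
        if name in NATIVE_FAMILIES:
            blocks[name] = compute_native(records, name)
        elif name in import_paths:
            blocks[name] = import_block(import_paths[name], name, records)
        else:
            raise RegistryError(f"no source configured for family {name!r}")
    return blocks
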