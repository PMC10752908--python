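import numpy as np
import pytest

from stackqsar.curation import curate
from stackqsar.descriptors import build_blocks
from stackqsar.synthetic import SyntheticSpec, gen_labeled_smiles, gen_imported_fp_files
from stackqsar.curation import CompoundRecord, read_compound_table, stratified_split


@pytest.fixture(scope="session")
def small_spec():
    """Small planted-motif generation conditions shared by unit tests."""
    return SyntheticSpec(n_active=40, n_inactive=40, label_noise=0.0, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_spec, tmp_path_factory):
    """Curated 80-compound dataset with deterministic motif signal."""
    path = tmp_path_factory.mktemp("data") / "table.csv"
    gen_labeled_smiles(small_spec).to_csv(path, index=False)
    return curate(read_compound_table(path))


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return stratified_split(small_dataset, 0.8, seed=5)


@pytest.fixture(scope="session")
def small_blocks(small_spec, small_split, tmp_path_factory):
    """MACCS (native, motif signal) + FP4 (planted ρ=0.6) + Pubchem (noise)."""
    train, test = small_split
    out = tmp_path_factory.mktemp("fps")
    blocks = {}
    for name, ds in (("train", train), ("test", test)):
        b = build_blocks(ds.records, ["MACCS"])
        paths = gen_imported_fp_files(
            small_spec, ds, ["FP4", "Pubchem"], out / name,
            correlations={"FP4": 0.6, "Pubchem": 0.0},
        )
        b.update(build_blocks(ds.records, ["FP4", "Pubchem"], paths))
        blocks[name] = b
    return blocks


@pytest.fixture()
def separable_block():
    """60×12 binary block whose first column equals the label exactly."""
    rng = np.random.default_rng(42)
    y = np.array([1] * 30 + [0] * 30)
    X = rng.integers(0, 2, size=(60, 12)).astype(float)
    X[:, 0] = y
    return X, y


def make_records(n, prefix="R"):
    """Cheap placeholder records (unique alkane SMILES) for split/alignment tests."""
    return [
        CompoundRecord(id=f"{prefix}{i}", smiles_raw="C" * (i + 1),
                       smiles_canonical="C" * (i + 1))
        for i in range(n)
    ]
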