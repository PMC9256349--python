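import numpy as np
import pytest

import dbpkit as dk


def make_feature_table(seed=0, n_per_class=20, d=10, effect=0.0,
                       informative=5, categories=None, length_range=(50, 80)):
    """Assembled feature table from one synthetic dataset."""
    spec = dk.SyntheticSpec(
        n_pos=n_per_class, n_neg=n_per_class, d=d,
        length_range=length_range, informative_dims=informative,
        effect_size=effect, noise_sd=1.0, seed=seed,
    )
    records, matrices, labels = dk.generate_dataset(spec)
    pairs = [(r, dk.sigmoid_normalize(m)) for r, m in zip(records, matrices)]
    fspec = dk.FeatureSetSpec(
        d=d, categories=tuple(categories) if categories else
        ("avg", "sep", "aa", "corr"))
    return dk.build_table(pairs, labels, fspec)


def make_study_tables(seed=0, n_per_class=30, d_emb=16, effect=1.5):
    """Six feature sets mirroring the study layout: two PSSM-derived sets
    (full + avg-only each) and an embedding-derived pair."""
    tables = {}
    layouts = [("PSSMR", "pssm", 20), ("PSSMS", "pssm", 20),
               ("ESM", "embedding", d_emb)]
    for i, (prefix, kind, d) in enumerate(layouts):
        spec = dk.SyntheticSpec(
            n_pos=n_per_class, n_neg=n_per_class, d=d,
            length_range=(50, 80), informative_dims=5, effect_size=effect,
            noise_sd=1.0, seed=seed + i, kind=kind)
        records, matrices, labels = dk.generate_dataset(spec)
        pairs = [(r, dk.sigmoid_normalize(m))
                 for r, m in zip(records, matrices)]
        tables[f"{prefix}_All"] = dk.build_table(
            pairs, labels, dk.FeatureSetSpec(d=d))
        tables[f"{prefix}_Avg"] = dk.build_table(
            pairs, labels, dk.FeatureSetSpec(d=d, categories=("avg",)))
    return tables


@pytest.fixture(scope="session")
def small_table():
    """40 proteins x 290 features, moderate planted signal."""
    return make_feature_table(seed=7, n_per_class=20, d=10, effect=2.0)


@pytest.fixture(scope="session")
def null_table():
    """40 proteins x 290 features, no class signal."""
    return make_feature_table(seed=11, n_per_class=20, d=10, effect=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def normalized_matrix(rng):
    values = rng.normal(size=(60, 8))
    raw = dk.ResidueMatrix(protein_id="m", source_kind="embedding",
                           values=values)
    return dk.sigmoid_normalize(raw)
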