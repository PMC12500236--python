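import itertools

import numpy as np
import pandas as pd
import pytest

import newsecm as ne


def make_table(values, sample_meta, protein_ids=None, genes=None, species=None,
               categories=None):
    """Small helper to assemble a ProteinQuantTable from plain lists.

    ``values``: 2-d array proteins x samples; ``sample_meta``: dict of
    sample id -> (model, treatment, fraction, replicate).
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    protein_ids = protein_ids or [f"P{i:03d}_HUMAN" for i in range(n)]
    samples = pd.DataFrame.from_dict(
        {
            s: dict(zip(("model", "treatment", "fraction", "replicate"), meta))
            for s, meta in sample_meta.items()
        },
        orient="index",
    ).rename_axis("sample")
    intensities = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                               columns=list(sample_meta))
    ann = pd.DataFrame(
        {
            "gene": genes or [f"G{i:03d}" for i in range(n)],
            "species": species or ["human"] * n,
            "division": [ne.io.CATEGORY_DIVISION.get(c, "non-matrisome") if categories else "non-matrisome"
                         for c in (categories or ["none"] * n)],
            "category": categories or ["none"] * n,
        },
        index=intensities.index,
    )
    return ne.ProteinQuantTable(intensities, samples, ann)


@pytest.fixture(scope="session")
def decm_dataset():
    """dECM-tumor preset at the standard benchmark size (seeded)."""
    return ne.generate_proteome_dataset(ne.decm_tumor_preset(seed=0, n_proteins=2000))


@pytest.fixture(scope="session")
def tumoroid_dataset():
    return ne.generate_proteome_dataset(ne.tumoroid_preset(seed=0, n_proteins=2000))


@pytest.fixture(scope="session")
def cross_model_dataset():
    return ne.generate_proteome_dataset(ne.cross_model_preset(seed=0, n_proteins=2000))


def pairwise_r2(table):
    """Mean pairwise Pearson r^2 among labeled-eluate profiles, split into
    same-model and cross-model pairs."""
    log2m = ne.log2_transform(table)
    corr = ne.correlation_matrix(log2m.values)
    meta = table.samples
    within, between = [], []
    for a, b in itertools.combinations(log2m.values.columns, 2):
        r2 = corr.r.loc[a, b] ** 2
        (within if meta.loc[a, "model"] == meta.loc[b, "model"] else between).append(r2)
    return float(np.mean(within)), float(np.mean(between))
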