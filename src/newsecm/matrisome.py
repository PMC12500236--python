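"""Matrisome category summaries, species recovery, contaminant accounting.

These are the enrichment quality-control readouts for a chemoselective
pull-down experiment: per-category protein counts and intensity proportions
compared between eluates (enriched newly synthesized ECM) and inputs (bulk
ECM extract); per-species eluate-to-input intensity recovery in mixed
human/rat tissues; and the intensity share of intracellular contaminant
families (actins, tubulins, histones) in the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CATEGORY_DIVISION, CATEGORY_NONE, ProteinQuantTable

#: gene-symbol prefixes for the intracellular contaminant families; curated
#: and overridable (the families are actins, tubulins and histones).
CONTAMINANT_PREFIXES = (
    "ACTA", "ACTB", "ACTC", "ACTG",  # actins
    "TUBA", "TUBB", "TUBD", "TUBE", "TUBG",  # tubulins
    "HIST", "H1-", "H2A", "H2B", "H3", "H4",  # histones
)

ALL_CATEGORIES = tuple(CATEGORY_DIVISION)


@dataclass
class MatrisomeSummary:
    """Per-category counts and intensity proportions for eluate vs input.

    ``counts``/``proportions`` are category x fraction frames;
    ``count_difference`` and ``proportion_ratio`` compare eluate to input.
    Proportions within one fraction sum to 1 over all categories including
    non-matrisome.
    """

    counts: pd.DataFrame
    proportions: pd.DataFrame
    count_difference: pd.Series
    proportion_ratio: pd.Series


def _category_series(table: ProteinQuantTable) -> pd.Series:
    cats = table.annotations.loc[table.intensities.index, "category"]
    return cats.where(cats.isin(ALL_CATEGORIES), CATEGORY_NONE)


def category_summary(
    table: ProteinQuantTable,
    fractions: tuple[str, str] = ("eluate", "input"),
    min_nonzero: int = 1,
    treatment: str | None = None,
) -> MatrisomeSummary:
    """Category counts and intensity proportions per fraction.

    A protein counts as *identified* in a fraction when it is nonzero in at
    least ``min_nonzero`` of that fraction's samples.  The intensity
    proportion of a category is its summed intensity divided by the
    all-protein sum, computed per sample and averaged over the fraction's
    samples.  ``treatment`` optionally restricts the samples considered
    (e.g. to the labeled arms only).
    """
    cats = _category_series(table)
    counts = {}
    props = {}
    for fraction in fractions:
        criteria = {"fraction": fraction}
        if treatment is not None:
            criteria["treatment"] = treatment
        samples = table.matching_samples(**criteria)
        if not samples:
            raise ValueError(f"no samples with fraction {fraction!r} in the table metadata")
        block = table.intensities.loc[:, samples]
        identified = (block > 0).sum(axis=1) >= min_nonzero
        counts[fraction] = identified.groupby(cats).sum()
        per_sample_prop = block.div(block.sum(axis=0), axis=1)
        props[fraction] = per_sample_prop.groupby(cats).sum().mean(axis=1)
    counts_df = pd.DataFrame(counts).reindex(ALL_CATEGORIES).fillna(0).astype(int)
    props_df = pd.DataFrame(props).reindex(ALL_CATEGORIES).fillna(0.0)
    eluate, inp = fractions
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = props_df[eluate] / props_df[inp]
    return MatrisomeSummary(
        counts=counts_df,
        proportions=props_df,
        count_difference=counts_df[eluate] - counts_df[inp],
        proportion_ratio=ratio.rename("eluate_over_input"),
    )


def species_recovery(
    eluate_table: ProteinQuantTable,
    input_table: ProteinQuantTable,
    per_sample_mean: bool = True,
) -> pd.DataFrame:
    """Per-species eluate-to-input intensity recovery and eluate shares.

    recovery_percent = 100 * (species eluate sum) / (species input sum),
    with sums taken as per-sample means by default so unequal replicate
    numbers do not distort the ratio (``per_sample_mean=False`` pools raw
    sums instead).  The two tables must be on a comparable intensity scale
    (raw, or jointly normalized).  eluate_share_percent is the species'
    share of total eluate intensity; shares sum to 100.  A species with zero
    input intensity gets recovery NaN and ``undefined_recovery=True``.
    """

    def species_sums(table: ProteinQuantTable) -> pd.Series:
        sp = table.annotations.loc[table.intensities.index, "species"]
        sums = table.intensities.groupby(sp).sum()
        return sums.mean(axis=1) if per_sample_mean else sums.sum(axis=1)

    elu = species_sums(eluate_table)
    inp = species_sums(input_table)
    species = sorted(set(elu.index) | set(inp.index))
    elu = elu.reindex(species).fillna(0.0)
    inp = inp.reindex(species).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        recovery = 100.0 * elu / inp
    recovery[inp == 0] = np.nan
    share = 100.0 * elu / elu.sum() if elu.sum() > 0 else elu * np.nan
    return pd.DataFrame(
        {
            "eluate_sum": elu,
            "input_sum": inp,
            "recovery_percent": recovery,
            "eluate_share_percent": share,
            "undefined_recovery": inp == 0,
        }
    ).rename_axis("species")


def is_contaminant_gene(
    gene: str, prefixes: Sequence[str] = CONTAMINANT_PREFIXES
) -> bool:
    return isinstance(gene, str) and gene.upper().startswith(tuple(prefixes))


def contaminant_share(
    table: ProteinQuantTable,
    prefixes: Sequence[str] = CONTAMINANT_PREFIXES,
    per_model: bool = True,
) -> pd.Series:
    """Percent of total intensity from contaminant-family proteins.

    Intended for input (bulk) fractions: 100 * (summed intensity of proteins
    whose gene symbol matches a family prefix) / (total intensity), reported
    per model when ``per_model`` (else one pooled value under ``'all'``).
    """
    genes = table.annotations.loc[table.intensities.index, "gene"]
    mask = genes.map(lambda g: is_contaminant_gene(g, prefixes)).to_numpy()
    groups = (
        table.samples.loc[table.sample_ids, "model"].unique().tolist()
        if per_model
        else ["all"]
    )
    out = {}
    for model in groups:
        samples = (
            table.matching_samples(model=model) if per_model else table.sample_ids
        )
        block = table.intensities.loc[:, samples]
        total = float(block.to_numpy().sum())
        cont = float(block.loc[mask].to_numpy().sum())
        out[model] = 100.0 * cont / total if total > 0 else np.nan
    return pd.Series(out, name="contaminant_percent").rename_axis("model")
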