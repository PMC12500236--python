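"""Headline summary statistics recomputed end-to-end from synthetic data.

Each helper generates (or takes) a preset dataset and pushes it through the
same pipeline stages a real experiment would use — Grubbs cleaning and
fold ratios for enrichment, pooled species sums for recovery, gene-family
matching for contaminants, per-sample proportion averages for matrisome
composition, pairwise-complete Pearson correlations for replicate
consistency.  Used by the acceptance machinery and handy for quick sanity
checks of a configuration.
"""

from __future__ import annotations

import itertools

import numpy as np

from .io import ProteinQuantTable
from .matrisome import category_summary, contaminant_share, species_recovery
from .pipeline import PipelineConfig, run_enrichment_qc
from .simulate import (
    ProteomeSimConfig,
    cross_model_preset,
    decm_tumor_preset,
    generate_proteome_dataset,
    tumoroid_preset,
)
from .stats import correlation_matrix, log2_transform


def enrichment_folds(config: ProteomeSimConfig) -> dict[str, float]:
    """Labeled/vehicle protein-group and total-intensity folds per model."""
    table, _ = generate_proteome_dataset(config)
    qc = run_enrichment_qc(table, PipelineConfig(seed=config.seed))
    out = {}
    for model, rep in qc["models"].items():
        out[f"{model}_protein_group_fold"] = rep["protein_group_fold"]
        out[f"{model}_intensity_fold"] = rep["intensity_fold"]
    return out


def recovery_and_contaminants(config: ProteomeSimConfig) -> dict[str, float]:
    """Species recovery percentages, rat eluate share, contaminant share."""
    table, _ = generate_proteome_dataset(config)
    model = config.models[0].name
    eluate = table.select_samples(model=model, fraction="eluate", treatment="labeled")
    inputs = table.select_samples(model=model, fraction="input")
    rec = species_recovery(eluate, inputs)
    out = {"contaminant_share_percent": float(contaminant_share(inputs).loc[model])}
    for species in rec.index:
        out[f"{species}_recovery_percent"] = float(rec.loc[species, "recovery_percent"])
        out[f"{species}_eluate_share_percent"] = float(
            rec.loc[species, "eluate_share_percent"]
        )
    return out


def matrisome_proportion_ratios(config: ProteomeSimConfig) -> dict[str, float]:
    """Eluate/input intensity-proportion ratios per matrisome category."""
    table, _ = generate_proteome_dataset(config)
    model = config.models[0].name
    labeled = table.select_samples(model=model, treatment="labeled")
    summ = category_summary(labeled, treatment="labeled")
    return {cat: float(summ.proportion_ratio[cat]) for cat in summ.proportion_ratio.index}


def replicate_r2(config: ProteomeSimConfig) -> dict[str, float]:
    """Mean pairwise Pearson r^2 of labeled-eluate log2 profiles, split
    into same-model and cross-model sample pairs."""
    table, _ = generate_proteome_dataset(config)
    log2m = log2_transform(table)
    corr = correlation_matrix(log2m.values)
    meta = table.samples
    within, between = [], []
    for a, b in itertools.combinations(log2m.values.columns, 2):
        r2 = corr.r.loc[a, b] ** 2
        (within if meta.loc[a, "model"] == meta.loc[b, "model"] else between).append(r2)
    out = {"within_model_r2": float(np.mean(within))}
    if between:
        out["between_model_r2"] = float(np.mean(between))
    return out
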