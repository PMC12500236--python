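"""Orchestration of the three analysis tracks.

* enrichment quality control: Grubbs-cleaned protein-group counts and total
  intensities per eluate arm, labeled/vehicle fold ratios, one-way ANOVA
  with Tukey HSD across arms, species recovery and contaminant share;
* differential analysis: normalize -> prefilter -> log2 -> (optional QRILC
  imputation) -> Welch t + permutation FDR -> geometric-mean fold changes ->
  volcano classification, plus the pairwise Pearson correlation matrix;
* image quantification: per-image tissue map + in/out channel means +
  normalized signals.

Each runner is a plain function over in-memory objects; the CLI in
:mod:`newsecm.cli` is a thin file-level wrapper around them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ProteinQuantTable, write_frame
from .matrisome import contaminant_share, species_recovery
from .normalize import (
    NormalizationScheme,
    grubbs_outliers,
    prefilter_min_nonzero,
    total_intensity_normalize,
)
from .stats import (
    Log2Matrix,
    QrilcParams,
    classify_volcano,
    correlation_matrix,
    log2_transform,
    p_cutoff_for_q,
    permutation_fdr,
    qrilc_impute,
)
from . import imaging

logger = logging.getLogger(__name__)

ELUATE = "eluate"
INPUT = "input"
LABELED = "labeled"
VEHICLE = "vehicle"


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs shared by the pipeline runners."""

    seed: int = 0
    normalization_mode: str = "within-group"
    prefilter_k: int = 2
    impute: bool = True
    n_permutations: int = 10_000
    q_threshold: float = 0.05
    fc_threshold: float = 1.0  # log2 units
    grubbs_alpha: float = 0.05
    qrilc: QrilcParams = field(default_factory=QrilcParams)
    image_threshold: float = 0.15
    image_min_size: int = 50
    image_disk_radius: int = 25

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> list[str]:
        return [f"config_hash={self.hash()}", f"seed={self.seed}"]


# ---------------------------------------------------------------------------
# enrichment QC


def _grubbs_clean(values: pd.Series, alpha: float) -> pd.Series:
    """Drop Grubbs outliers when the arm is large enough to test (n >= 3)."""
    if len(values) < 3:
        return values
    outliers = grubbs_outliers(values.to_numpy(dtype=float), alpha=alpha)
    keep = [i for i in range(len(values)) if i not in outliers]
    return values.iloc[keep]


def run_enrichment_qc(
    table: ProteinQuantTable, config: PipelineConfig | None = None
) -> dict:
    """Enrichment quality control on raw (pre-normalization) intensities.

    Per model: Grubbs-cleaned per-sample protein-group counts and total
    intensities in the eluates, labeled/vehicle fold ratios, and (when
    input samples are present) species recovery and contaminant share.
    Across all eluate arms: one-way ANOVA with Tukey HSD on the counts.
    """
    config = config or PipelineConfig()
    report: dict = {"models": {}, "config_hash": config.hash(), "seed": config.seed}
    arm_counts: dict[tuple[str, str], pd.Series] = {}

    for model in table.samples.loc[table.sample_ids, "model"].unique():
        model_report: dict = {}
        eluate = table.select_samples(model=model, fraction=ELUATE)
        arms = {}
        for treatment in (LABELED, VEHICLE):
            sample_ids = eluate.matching_samples(treatment=treatment)
            if not sample_ids:
                continue
            sub = eluate.select_samples(sample_ids)
            counts = _grubbs_clean(sub.nonzero_counts(), config.grubbs_alpha)
            totals = _grubbs_clean(sub.sample_totals(), config.grubbs_alpha)
            arms[treatment] = {"counts": counts, "totals": totals}
            arm_counts[(model, treatment)] = counts
        if LABELED not in arms:
            raise ValueError(f"model {model!r} has no labeled eluate samples")
        model_report["counts_per_sample"] = {
            t: arm["counts"].to_dict() for t, arm in arms.items()
        }
        if VEHICLE in arms:
            model_report["protein_group_fold"] = float(
                arms[LABELED]["counts"].mean() / arms[VEHICLE]["counts"].mean()
            )
            model_report["intensity_fold"] = float(
                arms[LABELED]["totals"].mean() / arms[VEHICLE]["totals"].mean()
            )

        input_samples = table.matching_samples(model=model, fraction=INPUT)
        if input_samples:
            labeled_eluate = table.select_samples(
                model=model, fraction=ELUATE, treatment=LABELED
            )
            inputs = table.select_samples(input_samples)
            model_report["species_recovery"] = species_recovery(labeled_eluate, inputs)
            model_report["contaminant_share_percent"] = float(
                contaminant_share(inputs, per_model=False).iloc[0]
            )
        report["models"][model] = model_report

    if len(arm_counts) >= 3:
        groups = [c.to_numpy(dtype=float) for c in arm_counts.values()]
        anova = sps.f_oneway(*groups)
        tukey = sps.tukey_hsd(*groups)
        names = [f"{m}:{t}" for m, t in arm_counts]
        pairs = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs[f"{names[i]} vs {names[j]}"] = float(tukey.pvalue[i, j])
        report["anova"] = {
            "f": float(anova.statistic),
            "p": float(anova.pvalue),
            "tukey_p": pairs,
        }
    return report


# ---------------------------------------------------------------------------
# differential analysis


@dataclass
class DifferentialReport:
    """Differential comparison output.

    ``results`` has one row per testable protein (log2FC of A over B, Welch
    t/p, permutation q, volcano class, per-group imputation counts);
    ``qualitative`` holds the proteins excluded by the detection prefilter
    with their group mean intensities; ``correlations`` is the pairwise
    Pearson matrix over the comparison's samples.
    """

    results: pd.DataFrame
    qualitative: pd.DataFrame
    class_counts: dict
    p_cutoff: float | None
    correlations: "object"
    n_permutations: int


def run_differential(
    table: ProteinQuantTable,
    group_a: Mapping[str, object],
    group_b: Mapping[str, object],
    config: PipelineConfig | None = None,
) -> DifferentialReport:
    """Two-group differential comparison A vs B defined by metadata predicates."""
    config = config or PipelineConfig()
    samples_a = table.matching_samples(**group_a)
    samples_b = table.matching_samples(**group_b)
    if not samples_a or not samples_b:
        raise ValueError(
            f"comparison groups resolve to {len(samples_a)} vs {len(samples_b)} samples"
        )
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"groups overlap on samples: {sorted(overlap)}")

    logger.info("differential: %d vs %d samples", len(samples_a), len(samples_b))
    sub = table.select_samples(samples_a + samples_b)
    scheme = NormalizationScheme.from_mode(config.normalization_mode)
    normalized = total_intensity_normalize(sub, scheme)

    testable, qualitative = prefilter_min_nonzero(
        normalized, samples_a, samples_b, k=config.prefilter_k
    )
    logger.info(
        "prefilter: %d testable, %d qualitative proteins",
        testable.n_proteins,
        qualitative.n_proteins,
    )

    log2m = log2_transform(testable)
    if config.impute:
        log2m = qrilc_impute(log2m, config.qrilc, seed=config.seed)
    values = log2m.values

    # log2FC = difference of mean log2 intensities = log2 of the ratio of
    # geometric means on the decimal scale; without imputation the means use
    # observed values only (the prefilter guarantees >= k per group).
    log2fc = values.loc[:, samples_a].mean(axis=1, skipna=True) - values.loc[
        :, samples_b
    ].mean(axis=1, skipna=True)
    fdr = permutation_fdr(
        values,
        [s in samples_a for s in values.columns],
        n_permutations=config.n_permutations,
        seed=config.seed,
    )

    classes = [
        classify_volcano(fc, qv, config.fc_threshold, config.q_threshold)
        for fc, qv in zip(log2fc, fdr.q)
    ]
    ann = testable.annotations
    results = pd.DataFrame(
        {
            "gene": ann["gene"],
            "species": ann["species"],
            "category": ann["category"],
            "log2fc": log2fc,
            "t": fdr.t,
            "p": fdr.p,
            "q": fdr.q,
            "volcano_class": classes,
            "n_imputed_a": log2m.n_imputed(samples_a),
            "n_imputed_b": log2m.n_imputed(samples_b),
        }
    )
    qual_df = pd.DataFrame(
        {
            "gene": qualitative.annotations["gene"],
            "mean_a": qualitative.intensities.loc[:, samples_a].mean(axis=1),
            "mean_b": qualitative.intensities.loc[:, samples_b].mean(axis=1),
        }
    )
    class_counts = pd.Series(classes).value_counts().to_dict()
    corr = correlation_matrix(log2_transform(testable).values)
    return DifferentialReport(
        results=results,
        qualitative=qual_df,
        class_counts=class_counts,
        p_cutoff=p_cutoff_for_q(results["p"].to_numpy(), results["q"].to_numpy(), config.q_threshold),
        correlations=corr,
        n_permutations=fdr.n_permutations,
    )


# ---------------------------------------------------------------------------
# image quantification


def run_image_quant(
    images: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    config: PipelineConfig | None = None,
    channels: Sequence[str] = ("red", "green"),
) -> tuple[pd.DataFrame, dict[str, imaging.TissueMap]]:
    """Tissue-map quantification for a batch of RGB images.

    Returns a per-image report (tissue area, per-channel in/out means,
    area-normalized signal) and the masks.
    """
    config = config or PipelineConfig()
    if not isinstance(images, Mapping):
        images = {f"image_{i}": img for i, img in enumerate(images)}
    if not images:
        raise ValueError("no images supplied")
    rows = []
    masks: dict[str, imaging.TissueMap] = {}
    for image_id, image in images.items():
        split = imaging.split_channels(image)
        tissue = imaging.build_dapi_map(
            split["blue"],
            threshold=config.image_threshold,
            min_size=config.image_min_size,
            disk_radius=config.image_disk_radius,
        )
        masks[image_id] = tissue
        row = {
            "image": image_id,
            "threshold": tissue.threshold,
            "min_size": tissue.min_size,
            "disk_radius": tissue.disk_radius,
            "tissue_area": tissue.area,
        }
        for channel in channels:
            region = imaging.region_mean_intensity(split[channel], tissue)
            row[f"{channel}_in_mean"] = region.inside_mean
            row[f"{channel}_out_mean"] = region.outside_mean
            row[f"{channel}_area_normalized"] = imaging.normalized_signal(
                region, tissue, mode="area"
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("image"), masks


# ---------------------------------------------------------------------------
# output helpers


def write_report_frames(
    frames: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write result frames as CSV with a config-hash + seed header."""
    out_dir = Path(out_dir)
    return {
        name: write_frame(df, out_dir / f"{name}.csv", config.header(), overwrite)
        for name, df in frames.items()
    }
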