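"""Synthetic LFQ proteomes and fluorescence images with known ground truth.

The proteome generator emulates the statistical structure of a
chemoselective newsECM enrichment experiment so that every downstream stage
(enrichment quality control, species recovery, matrisome accounting,
differential statistics) can be validated against a configured truth:

* per-protein abundances are lognormal (log2-normal) with a shared
  protein effect, an optional model-level effect and replicate noise, so
  that within-model and between-model replicate correlations hit configured
  R^2 targets;
* labeled vs vehicle eluates differ through two mechanisms — extra detected
  protein groups in the labeled arm (detection enrichment) and per-protein
  intensity scaling (intensity enrichment) — calibrated exactly on the
  pre-censoring truth means;
* mixed human/rat composition with configured eluate/input recovery per
  species, contaminant-family intensity share, and matrisome category
  proportion shifts between inputs and eluates, calibrated so the
  *expected observed* (post-censoring) statistics match the configuration;
* missing-not-at-random dropout: each sample left-censors values around its
  own low-intensity quantile with a soft sigmoidal boundary, so dropout
  probability is monotone non-increasing in abundance.

The image generator produces RGB fields with nuclei (blue channel) confined
to a blob-shaped tissue region, plus signal channels with configured
in/out-of-tissue means, and returns the pixel-wise tissue mask as truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, ndtri

from .io import (
    CATEGORY_DIVISION,
    CATEGORY_NONE,
    MATRISOME_CATEGORIES,
    ProteinQuantTable,
    SPECIES_HUMAN,
    SPECIES_RAT,
)

LABELED = "labeled"
VEHICLE = "vehicle"
ELUATE = "eluate"
INPUT = "input"


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


# ---------------------------------------------------------------------------
# configuration

#: curated contaminant gene symbols (actin / tubulin / histone families)
CONTAMINANT_GENES = (
    "ACTB", "ACTG1", "ACTA2", "ACTC1", "ACTG2", "ACTA1",
    "TUBA1A", "TUBA1B", "TUBA4A", "TUBB", "TUBB4B", "TUBB6",
    "TUBG1", "TUBA8", "TUBB2A", "TUBB3", "TUBB2B", "TUBA1C",
    "HIST1H1C", "HIST1H1E", "HIST1H2BK", "HIST2H2AC", "HIST1H4A",
    "H2AFZ", "H2AFY", "H3F3A", "HIST1H2AB", "HIST1H2BC", "HIST1H3A",
    "HIST1H1B",
)


@dataclass(frozen=True)
class CategoryProfile:
    """Matrisome composition of the simulated human proteome.

    ``counts``: number of proteins per category; ``input_share``: category
    share of the *human input* intensity (the remainder is non-matrisome);
    ``eluate_ratio``: target eluate/input ratio of the category's intensity
    proportion (relative to all identified proteins).
    """

    counts: Mapping[str, int]
    input_share: Mapping[str, float]
    eluate_ratio: Mapping[str, float]

    def validate(self) -> None:
        for cat in self.counts:
            if cat not in MATRISOME_CATEGORIES:
                raise ConfigurationError(f"categories.counts: unknown category {cat!r}")
        share_sum = sum(self.input_share.values())
        if not 0 < share_sum < 1:
            raise ConfigurationError(
                "categories.input_share must sum to a value in (0, 1) "
                "(the remainder is non-matrisome)"
            )
        for cat, ratio in self.eluate_ratio.items():
            if ratio <= 0:
                raise ConfigurationError(f"categories.eluate_ratio[{cat!r}] must be > 0")


def default_category_profile() -> CategoryProfile:
    """Collagen-dominated bulk-ECM input with the dECM-tumor eluate shifts."""
    return CategoryProfile(
        counts={
            "collagens": 40,
            "ecm_glycoproteins": 100,
            "proteoglycans": 30,
            "ecm_regulators": 100,
            "ecm_affiliated": 80,
            "secreted_factors": 120,
        },
        input_share={
            "collagens": 0.20,
            "ecm_glycoproteins": 0.12,
            "proteoglycans": 0.02,
            "ecm_regulators": 0.04,
            "ecm_affiliated": 0.03,
            "secreted_factors": 0.01,
        },
        eluate_ratio={
            "collagens": 0.26,
            "ecm_glycoproteins": 1.5,
            "proteoglycans": 2.9,
            "ecm_regulators": 2.0,
            "ecm_affiliated": 2.5,
            "secreted_factors": 9.2,
        },
    )


@dataclass(frozen=True)
class ModelSimParams:
    """Per-tissue-model arm sizes and enrichment/recovery targets."""

    name: str
    n_labeled_eluate: int = 5
    n_vehicle_eluate: int = 3
    n_input: int = 5
    detection_enrichment: float = 5.3
    intensity_enrichment: float = 23.4
    human_input_share: float = 1.0
    human_recovery: float = 0.875
    rat_recovery: float = 0.30
    n_rat_proteins: int = 0
    contaminant_share: float | None = None
    n_contaminant_proteins: int = 30
    categories: CategoryProfile | None = None
    include_inputs: bool = True
    include_vehicle: bool = True

    def validate(self) -> None:
        if self.detection_enrichment <= 0:
            raise ConfigurationError("detection_enrichment must be > 0")
        if self.intensity_enrichment <= 0:
            raise ConfigurationError("intensity_enrichment must be > 0")
        for fieldname in ("human_input_share", "human_recovery", "rat_recovery"):
            value = getattr(self, fieldname)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{fieldname} must lie in [0, 1], got {value}")
        if self.contaminant_share is not None and not 0 <= self.contaminant_share < 1:
            raise ConfigurationError("contaminant_share must lie in [0, 1)")
        if self.include_vehicle and self.n_vehicle_eluate < 2:
            raise ConfigurationError("n_vehicle_eluate must be >= 2 per arm")
        if self.n_labeled_eluate < 2:
            raise ConfigurationError("n_labeled_eluate must be >= 2 per arm")
        if self.include_inputs and self.n_input < 2:
            raise ConfigurationError("n_input must be >= 2 per arm")
        if self.human_input_share < 1 and self.n_rat_proteins < 1:
            raise ConfigurationError(
                "n_rat_proteins must be >= 1 when human_input_share < 1"
            )
        if self.categories is not None:
            self.categories.validate()


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Study-level configuration for the proteome generator."""

    models: tuple[ModelSimParams, ...]
    n_proteins: int = 2000
    abundance_meanlog: float = 20.0  # log2 scale
    abundance_sdlog: float = 2.0  # log2 scale
    within_model_r2: float = 0.94
    between_model_r2: float = 0.49
    noise_sdlog: float | None = None  # overrides the R^2-derived replicate noise
    censor_quantile: float = 0.15
    censor_softness: float = 0.3  # log2 units
    seed: int = 0

    def validate(self) -> None:
        if not self.models:
            raise ConfigurationError("models must list at least one tissue model")
        if self.n_proteins < 50:
            raise ConfigurationError("n_proteins must be >= 50")
        if not 0 <= self.censor_quantile < 1:
            raise ConfigurationError("censor_quantile must lie in [0, 1)")
        if self.censor_softness <= 0:
            raise ConfigurationError("censor_softness must be > 0")
        if not 0 < self.within_model_r2 <= 1:
            raise ConfigurationError("within_model_r2 must lie in (0, 1]")
        if not 0 < self.between_model_r2 <= 1:
            raise ConfigurationError("between_model_r2 must lie in (0, 1]")
        if self.between_model_r2 > self.within_model_r2:
            raise ConfigurationError("between_model_r2 cannot exceed within_model_r2")
        if self.abundance_sdlog <= 0:
            raise ConfigurationError("abundance_sdlog must be > 0")
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ConfigurationError("models must have distinct names")
        for m in self.models:
            m.validate()
        if len(self.models) > 1:
            for m in self.models:
                if m.human_input_share < 1:
                    raise ConfigurationError(
                        "multi-model configurations must be human-only "
                        f"(model {m.name!r} has human_input_share < 1)"
                    )


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic quantification table.

    ``proteins`` has one row per emitted protein (species, category, gene,
    contaminant flag, per-arm pre-censoring mean intensity, vehicle
    detectability); ``summary`` holds the realized truth-level statistics
    (enrichment folds computed from the truth means are exact);
    ``sample_sums`` are the realized per-sample intensity sums before
    censoring.
    """

    proteins: pd.DataFrame
    summary: dict
    sample_sums: pd.Series
    config: ProteomeSimConfig


# ---------------------------------------------------------------------------
# numerical helpers


def _gh_nodes(n: int = 31) -> tuple[np.ndarray, np.ndarray]:
    z, w = hermgauss(n)
    return z, w


def _mixture_quantile(means_log2: np.ndarray, sigma: float, q: float) -> float:
    """Quantile of the mixture N(mean_i, sigma^2) over proteins (log2 units)."""
    from scipy.stats import norm

    lo = means_log2.min() - 8 * sigma
    hi = means_log2.max() + 8 * sigma

    def cdf_minus_q(x: float) -> float:
        return float(norm.cdf((x - means_log2) / sigma).mean() - q)

    return optimize.brentq(cdf_minus_q, lo, hi, xtol=1e-9)


def _expected_observed(
    means_log2: np.ndarray,
    cutoff: float,
    sigma: float,
    softness: float,
    gh: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Expected observed (post-censoring) intensity per protein.

    E[2^(m + eps) * (1 - p_miss(m + eps))] with eps ~ N(0, sigma^2) and
    p_miss(v) = expit((cutoff - v) / softness), by Gauss-Hermite quadrature.
    """
    z, w = gh
    eps = math.sqrt(2.0) * sigma * z  # quadrature nodes in log2 units
    v = means_log2[:, None] + eps[None, :]
    keep = 1.0 - expit((cutoff - v) / softness)
    return (np.exp2(v) * keep) @ w / math.sqrt(math.pi)


def _latent_pair_correlation(
    target_r: float,
    censor_quantile: float,
    softness_std: float,
    grid_points: int = 241,
) -> float:
    """Latent bivariate-normal correlation whose post-censoring observed
    correlation equals ``target_r``.

    Both coordinates are soft-left-censored at the marginal
    ``censor_quantile`` point; the observed correlation is computed over the
    jointly retained mass on a standardized grid, and the latent correlation
    is found by root bisection.  With no censoring the identity is returned.
    """
    if censor_quantile <= 0:
        return target_r
    a = float(ndtri(censor_quantile))
    z = np.linspace(-6.0, 6.0, grid_points)
    keep = 1.0 - expit((a - z) / softness_std)
    X = z[:, None]
    Y = z[None, :]

    def observed(rho: float) -> float:
        det = 1.0 - rho * rho
        logw = -(X * X - 2.0 * rho * X * Y + Y * Y) / (2.0 * det)
        w = np.exp(logw) * keep[:, None] * keep[None, :]
        w /= w.sum()
        mx = float((w * X).sum())
        my = float((w * Y).sum())
        vx = float((w * (X - mx) ** 2).sum())
        vy = float((w * (Y - my) ** 2).sum())
        cov = float((w * (X - mx) * (Y - my)).sum())
        return cov / math.sqrt(vx * vy)

    if target_r <= 0:
        return target_r
    lo, hi = -0.3, 0.99995
    return float(optimize.brentq(lambda r: observed(r) - target_r, lo, hi, xtol=1e-6))


def _variance_components(config: ProteomeSimConfig) -> tuple[float, float, float]:
    """(sigma_protein^2, sigma_model^2, sigma_noise^2) in log2 units.

    The within/between R^2 targets refer to observed (post-censoring,
    pairwise-complete) replicate correlations, so the latent pair
    correlations are inflated to compensate for censoring attenuation.
    """
    var_total = config.abundance_sdlog**2
    if config.noise_sdlog is not None:
        var_noise = config.noise_sdlog**2
        if var_noise >= var_total:
            raise ConfigurationError("noise_sdlog must be smaller than abundance_sdlog")
        rho_w = 1.0 - var_noise / var_total
        rho_b = rho_w * math.sqrt(config.between_model_r2 / config.within_model_r2)
    else:
        softness_std = config.censor_softness / config.abundance_sdlog
        rho_w = _latent_pair_correlation(
            math.sqrt(config.within_model_r2), config.censor_quantile, softness_std
        )
        rho_b = _latent_pair_correlation(
            math.sqrt(config.between_model_r2), config.censor_quantile, softness_std
        )
    if not rho_b <= rho_w <= 1:
        raise ConfigurationError(
            "correlation targets are infeasible after censoring adjustment"
        )
    var_protein = rho_b * var_total if len(config.models) > 1 else rho_w * var_total
    var_model = (rho_w - rho_b) * var_total if len(config.models) > 1 else 0.0
    var_noise = (1.0 - rho_w) * var_total
    return var_protein, var_model, var_noise


# ---------------------------------------------------------------------------
# protein attribute assignment


def _assign_attributes(config: ProteomeSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    needs_rat = any(m.human_input_share < 1 for m in config.models)
    n_rat = max((m.n_rat_proteins for m in config.models), default=0) if needs_rat else 0
    needs_cont = any(m.contaminant_share is not None for m in config.models)
    n_cont = max(m.n_contaminant_proteins for m in config.models) if needs_cont else 0
    profile = next((m.categories for m in config.models if m.categories is not None), None)

    species = np.array([SPECIES_HUMAN] * n, dtype=object)
    category = np.array([CATEGORY_NONE] * n, dtype=object)
    gene = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    contaminant = np.zeros(n, dtype=bool)

    cursor = 0
    if n_rat:
        species[cursor : cursor + n_rat] = SPECIES_RAT
        cursor += n_rat
    if profile is not None:
        for cat, count in profile.counts.items():
            if cursor + count > n:
                raise ConfigurationError(
                    "n_proteins is too small for the requested category counts"
                )
            category[cursor : cursor + count] = cat
            cursor += count
    if n_cont:
        if cursor + n_cont > n:
            raise ConfigurationError("n_proteins is too small for the contaminant block")
        contaminant[cursor : cursor + n_cont] = True
        gene[cursor : cursor + n_cont] = [
            CONTAMINANT_GENES[i % len(CONTAMINANT_GENES)] for i in range(n_cont)
        ]
        cursor += n_cont

    division = np.array([CATEGORY_DIVISION[c] for c in category], dtype=object)
    protein_id = np.array(
        [
            f"SP{i:05d}_{'RAT' if species[i] == SPECIES_RAT else 'HUMAN'}"
            for i in range(n)
        ],
        dtype=object,
    )
    frame = pd.DataFrame(
        {
            "species": species,
            "category": category,
            "division": division,
            "gene": gene,
            "contaminant": contaminant,
        },
        index=pd.Index(protein_id, name="protein_id"),
    )
    return frame


# ---------------------------------------------------------------------------
# per-model mean calibration


def _calibrate_input_means(
    mu: np.ndarray,
    attrs: pd.DataFrame,
    model: ModelSimParams,
    sigma_noise: float,
    censor_quantile: float,
    softness: float,
    gh: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Scale attribute blocks of the input means to the configured composition.

    Species and category shares are calibrated exactly on the truth means;
    the contaminant share is calibrated on the expected observed
    (post-censoring) intensities because that is how the share is measured.
    """
    mu = mu.copy()
    human = (attrs["species"] == SPECIES_HUMAN).to_numpy()
    rat = ~human

    if model.categories is not None:
        shares = dict(model.categories.input_share)
        shares[CATEGORY_NONE] = 1.0 - sum(shares.values())
        human_total = mu[human].sum()
        for cat, share in shares.items():
            block = human & (attrs["category"] == cat).to_numpy()
            if block.sum() == 0:
                if share > 0:
                    raise ConfigurationError(
                        f"categories.input_share names {cat!r} but no proteins carry it"
                    )
                continue
            mu[block] *= share * human_total / mu[block].sum()

    if model.human_input_share < 1:
        rat_share = 1.0 - model.human_input_share
        mu[rat] *= rat_share / (1 - rat_share) * mu[human].sum() / mu[rat].sum()
    else:
        mu[rat] = 0.0

    if model.contaminant_share is not None:
        cont = attrs["contaminant"].to_numpy()
        target = model.contaminant_share
        for _ in range(4):  # fixed point: scaling shifts the censor threshold slightly
            present = mu > 0
            log2mu = np.log2(mu[present])
            cutoff = (
                _mixture_quantile(log2mu, sigma_noise, censor_quantile)
                if censor_quantile > 0
                else -np.inf
            )
            e_obs = _expected_observed(log2mu, cutoff, sigma_noise, softness, gh)
            obs = np.zeros_like(mu)
            obs[present] = e_obs
            current = obs[cont].sum()
            other = obs.sum() - current
            factor = (target / (1 - target)) * other / current
            mu[cont] *= factor
            if abs(factor - 1) < 1e-9:
                break
    return mu


def _calibrate_eluate_means(
    mu_input: np.ndarray,
    attrs: pd.DataFrame,
    model: ModelSimParams,
    sigma_noise: float,
    censor_quantile: float,
    softness: float,
    gh: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Labeled-eluate means from input means via species recovery and
    matrisome proportion shifts, calibrated on expected observed sums."""
    human = (attrs["species"] == SPECIES_HUMAN).to_numpy()
    rat = ~human
    recovery = np.where(human, model.human_recovery, model.rat_recovery)
    mu = mu_input * recovery

    def expected(mu_arr: np.ndarray) -> np.ndarray:
        present = mu_arr > 0
        log2mu = np.log2(mu_arr[present])
        cutoff = (
            _mixture_quantile(log2mu, sigma_noise, censor_quantile)
            if censor_quantile > 0
            else -np.inf
        )
        obs = np.zeros_like(mu_arr)
        obs[present] = _expected_observed(log2mu, cutoff, sigma_noise, softness, gh)
        return obs

    obs_in = expected(mu_input)
    in_total = obs_in.sum()
    in_human = obs_in[human].sum()
    in_rat = obs_in[rat].sum()

    cat_blocks = {}
    in_prop = {}
    if model.categories is not None:
        for cat in model.categories.eluate_ratio:
            block = human & (attrs["category"] == cat).to_numpy()
            cat_blocks[cat] = block
            in_prop[cat] = obs_in[block].sum() / in_total

    for _ in range(8):
        obs_el = expected(mu)
        f_h = model.human_recovery * in_human / obs_el[human].sum()
        mu[human] *= f_h
        obs_el[human] *= f_h
        if rat.any() and mu[rat].sum() > 0:
            f_r = model.rat_recovery * in_rat / obs_el[rat].sum()
            mu[rat] *= f_r
            obs_el[rat] *= f_r
        max_adj = max(abs(f_h - 1), abs(f_r - 1) if rat.any() and mu[rat].sum() > 0 else 0)
        if model.categories is not None:
            total = obs_el.sum()
            target_sum = sum(
                model.categories.eluate_ratio[c] * in_prop[c] for c in cat_blocks
            )
            if target_sum * total >= 0.98 * obs_el[human].sum():
                raise ConfigurationError(
                    "categories.eluate_ratio targets exceed the human eluate budget"
                )
            for cat, block in cat_blocks.items():
                target = model.categories.eluate_ratio[cat] * in_prop[cat] * total
                f_c = target / obs_el[block].sum()
                mu[block] *= f_c
                obs_el[block] *= f_c
                max_adj = max(max_adj, abs(f_c - 1))
        if max_adj < 1e-10:
            break
    return mu


# ---------------------------------------------------------------------------
# main generator


def generate_proteome_dataset(
    config: ProteomeSimConfig,
) -> tuple[ProteinQuantTable, SyntheticTruth]:
    """Generate a wide intensity table plus its ground truth.

    Zeros encode missing values; identical configs with identical seeds
    produce identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gh = _gh_nodes()
    attrs = _assign_attributes(config, rng)
    n = config.n_proteins
    var_protein, var_model, var_noise = _variance_components(config)
    sigma_noise = math.sqrt(var_noise)

    protein_effect = rng.normal(0.0, math.sqrt(var_protein), size=n)
    model_effects = {
        m.name: (
            rng.normal(0.0, math.sqrt(var_model), size=n) if var_model > 0 else np.zeros(n)
        )
        for m in config.models
    }

    arm_means: dict[tuple[str, str, str], np.ndarray] = {}
    summary: dict[str, dict] = {}
    for model in config.models:
        base = np.exp2(config.abundance_meanlog + protein_effect + model_effects[model.name])
        mu_in = _calibrate_input_means(
            base, attrs, model, sigma_noise, config.censor_quantile, config.censor_softness, gh
        )
        mu_el = _calibrate_eluate_means(
            mu_in, attrs, model, sigma_noise, config.censor_quantile, config.censor_softness, gh
        )
        arm_means[(model.name, LABELED, ELUATE)] = mu_el
        if model.include_inputs:
            arm_means[(model.name, LABELED, INPUT)] = mu_in

        model_summary = {
            "truth_human_recovery": float(
                mu_el[(attrs["species"] == SPECIES_HUMAN).to_numpy()].sum()
                / mu_in[(attrs["species"] == SPECIES_HUMAN).to_numpy()].sum()
            )
        }
        detectable = np.zeros(n, dtype=bool)
        if model.include_vehicle:
            m_detect = max(2, int(round(n / model.detection_enrichment)))
            idx = rng.choice(n, size=m_detect, replace=False)
            detectable[idx] = True
            mu_v = np.zeros(n)
            mu_v[detectable] = mu_el[detectable]
            mu_v *= mu_el.sum() / (model.intensity_enrichment * mu_v.sum())
            arm_means[(model.name, VEHICLE, ELUATE)] = mu_v
            model_summary.update(
                truth_detection_fold=n / m_detect,
                truth_intensity_fold=float(mu_el.sum() / mu_v.sum()),
            )
        attrs[f"vehicle_detectable_{model.name}"] = detectable
        attrs[f"mean_{model.name}_{LABELED}_{ELUATE}"] = mu_el
        if model.include_inputs:
            attrs[f"mean_{model.name}_{LABELED}_{INPUT}"] = mu_in
        if model.include_vehicle:
            attrs[f"mean_{model.name}_{VEHICLE}_{ELUATE}"] = arm_means[
                (model.name, VEHICLE, ELUATE)
            ]
        summary[model.name] = model_summary

    if len(config.models) == 2:
        a, b = (m.name for m in config.models)
        with np.errstate(divide="ignore", invalid="ignore"):
            attrs["true_log2fc"] = np.log2(
                arm_means[(a, LABELED, ELUATE)] / arm_means[(b, LABELED, ELUATE)]
            )

    # --- sample the table ------------------------------------------------
    columns: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    pre_censor_sums: dict[str, float] = {}
    for model in config.models:
        arms = [(LABELED, ELUATE, model.n_labeled_eluate)]
        if model.include_vehicle:
            arms.append((VEHICLE, ELUATE, model.n_vehicle_eluate))
        if model.include_inputs:
            arms.append((LABELED, INPUT, model.n_input))
        for treatment, fraction, n_rep in arms:
            mu = arm_means[(model.name, treatment, fraction)]
            present = mu > 0
            log2mu = np.log2(mu[present])
            for rep in range(1, n_rep + 1):
                sample = f"{model.name}_{treatment}_{fraction}_r{rep}"
                v = log2mu + rng.normal(0.0, sigma_noise, size=int(present.sum()))
                intensity = np.exp2(v)
                pre_censor_sums[sample] = float(intensity.sum())
                if config.censor_quantile > 0:
                    q_hat = np.quantile(v, config.censor_quantile)
                    p_miss = expit((q_hat - v) / config.censor_softness)
                    missing = rng.random(len(v)) < p_miss
                    intensity = np.where(missing, 0.0, intensity)
                col = np.zeros(n)
                col[present] = intensity
                columns[sample] = col
                meta_rows[sample] = {
                    "model": model.name,
                    "treatment": treatment,
                    "fraction": fraction,
                    "replicate": rep,
                }

    intensities = pd.DataFrame(columns, index=attrs.index)
    samples = pd.DataFrame.from_dict(meta_rows, orient="index").rename_axis("sample")

    order = rng.permutation(n)
    intensities = intensities.iloc[order]
    attrs = attrs.iloc[order]

    table = ProteinQuantTable(
        intensities,
        samples,
        attrs[["gene", "species", "division", "category"]].copy(),
    )
    truth = SyntheticTruth(
        proteins=attrs,
        summary=summary,
        sample_sums=pd.Series(pre_censor_sums, name="pre_censor_sum"),
        config=config,
    )
    return table, truth


# ---------------------------------------------------------------------------
# presets: the study conditions


def decm_tumor_preset(seed: int = 0, n_proteins: int = 2000) -> ProteomeSimConfig:
    """dECM-tumor arm: 5 labeled / 3 vehicle eluates, 5 inputs, mixed
    human/rat composition.

    Detection and intensity enrichment (5.3x and 23.4x labeled over
    vehicle), species recoveries (87.5% human, 30% rat), contaminant input
    share (0.36%) and matrisome proportion shifts are the study's reported
    summary statistics.  The rat share of input intensity (3.42%) is the
    value consistent with those recoveries and a residual rat eluate share
    of 1.2%.
    """
    return ProteomeSimConfig(
        models=(
            ModelSimParams(
                name="decm_tumor",
                n_labeled_eluate=5,
                n_vehicle_eluate=3,
                n_input=5,
                detection_enrichment=5.3,
                intensity_enrichment=23.4,
                human_input_share=1.0 - 0.0342,
                human_recovery=0.875,
                rat_recovery=0.30,
                n_rat_proteins=68,
                contaminant_share=0.0036,
                categories=default_category_profile(),
            ),
        ),
        n_proteins=n_proteins,
        seed=seed,
    )


def tumoroid_preset(seed: int = 0, n_proteins: int = 2000) -> ProteomeSimConfig:
    """ECM-free tumoroid arm: 5 labeled / 5 vehicle eluates, human-only.

    Detection and intensity enrichment are 9.0x and 11.0x; the contaminant
    input share is 0.81%.
    """
    return ProteomeSimConfig(
        models=(
            ModelSimParams(
                name="tumoroid",
                n_labeled_eluate=5,
                n_vehicle_eluate=5,
                n_input=5,
                detection_enrichment=9.0,
                intensity_enrichment=11.0,
                human_input_share=1.0,
                contaminant_share=0.0081,
                categories=default_category_profile(),
            ),
        ),
        n_proteins=n_proteins,
        seed=seed,
    )


def cross_model_preset(seed: int = 0, n_proteins: int = 2000) -> ProteomeSimConfig:
    """Cross-model comparison: labeled eluates only (4 dECM-tumor + 5
    tumoroid), human-only, with the replicate-correlation structure
    (within-model R^2 = 0.94, between-model R^2 = 0.49)."""
    return ProteomeSimConfig(
        models=(
            ModelSimParams(
                name="decm_tumor",
                n_labeled_eluate=4,
                include_inputs=False,
                include_vehicle=False,
            ),
            ModelSimParams(
                name="tumoroid",
                n_labeled_eluate=5,
                include_inputs=False,
                include_vehicle=False,
            ),
        ),
        n_proteins=n_proteins,
        within_model_r2=0.94,
        between_model_r2=0.49,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simple two-group generator for differential-power checks


def generate_two_group_dataset(
    n_proteins: int = 500,
    n_up: int = 50,
    n_down: int = 50,
    effect_log2: float = 3.0,
    n_per_group: int = 5,
    meanlog: float = 20.0,
    sdlog: float = 2.0,
    noise_sdlog: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Complete (uncensored) log2 two-group matrix with planted effects.

    Returns (log2 values frame, boolean group-A labels, truth frame with
    the per-protein true log2 fold change A - B).
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(meanlog, sdlog, size=n_proteins)
    effect = np.zeros(n_proteins)
    effect[:n_up] = effect_log2
    effect[n_up : n_up + n_down] = -effect_log2
    order = rng.permutation(n_proteins)
    base, effect = base[order], effect[order]
    a = base[:, None] + effect[:, None] + rng.normal(0, noise_sdlog, (n_proteins, n_per_group))
    b = base[:, None] + rng.normal(0, noise_sdlog, (n_proteins, n_per_group))
    index = pd.Index([f"P{i:05d}" for i in range(n_proteins)], name="protein_id")
    cols = [f"A_r{i+1}" for i in range(n_per_group)] + [f"B_r{i+1}" for i in range(n_per_group)]
    values = pd.DataFrame(np.hstack([a, b]), index=index, columns=cols)
    labels = np.array([True] * n_per_group + [False] * n_per_group)
    truth = pd.DataFrame({"true_log2fc": effect}, index=index)
    return values, labels, truth


# ---------------------------------------------------------------------------
# synthetic fluorescence images


@dataclass(frozen=True)
class ImageSimConfig:
    """Synthetic multi-channel fluorescence field with a blob-shaped tissue
    region, nuclei in the blue channel and configured in/out-of-tissue
    signal means (0-1 scale) in the red and green channels."""

    shape: tuple[int, int] = (256, 256)
    n_blobs: int = 3
    blob_radius: tuple[float, float] = (40.0, 65.0)
    n_nuclei: int = 350
    nucleus_radius: tuple[float, float] = (3.0, 6.0)
    in_tissue_mean: Mapping[str, float] = field(
        default_factory=lambda: {"red": 0.8, "green": 0.5}
    )
    out_tissue_mean: Mapping[str, float] = field(
        default_factory=lambda: {"red": 0.1, "green": 0.1}
    )
    nucleus_intensity: float = 0.9
    background: float = 0.02
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ConfigurationError("shape must have positive dimensions")
        for mapping, name in (
            (self.in_tissue_mean, "in_tissue_mean"),
            (self.out_tissue_mean, "out_tissue_mean"),
        ):
            for channel, value in mapping.items():
                if not 0 <= value <= 1:
                    raise ConfigurationError(f"{name}[{channel!r}] must lie in [0, 1]")
        if self.n_nuclei < 0:
            raise ConfigurationError("n_nuclei must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def generate_if_image(config: ImageSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate (rgb image HxWx3 float in [0,1], ground-truth tissue mask).

    Nuclei are placed inside the blob-shaped tissue region only; with
    ``n_nuclei=0`` there is no tissue and the truth mask is empty.  Same
    seed, same image.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    yy, xx = np.mgrid[0:h, 0:w]

    mask = np.zeros((h, w), dtype=bool)
    if config.n_nuclei > 0:
        r_lo, r_hi = config.blob_radius
        for _ in range(config.n_blobs):
            r = rng.uniform(r_lo, r_hi)
            cy = rng.uniform(r * 0.5, h - r * 0.5)
            cx = rng.uniform(r * 0.5, w - r * 0.5)
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    rgb = np.zeros((h, w, 3))
    channel_index = {"red": 0, "green": 1, "blue": 2}
    for channel in ("red", "green"):
        inside = config.in_tissue_mean.get(channel, 0.0)
        outside = config.out_tissue_mean.get(channel, 0.0)
        chan = np.where(mask, inside, outside) + rng.normal(0, config.noise_sd, (h, w))
        rgb[:, :, channel_index[channel]] = chan

    blue = np.full((h, w), config.background)
    if config.n_nuclei > 0 and mask.any():
        flat = np.flatnonzero(mask.ravel())
        centers = rng.choice(flat, size=config.n_nuclei, replace=True)
        cy, cx = np.unravel_index(centers, (h, w))
        radii = rng.uniform(*config.nucleus_radius, size=config.n_nuclei)
        for y0, x0, r in zip(cy, cx, radii):
            y_lo, y_hi = max(0, int(y0 - r - 1)), min(h, int(y0 + r + 2))
            x_lo, x_hi = max(0, int(x0 - r - 1)), min(w, int(x0 + r + 2))
            sub_y, sub_x = np.mgrid[y_lo:y_hi, x_lo:x_hi]
            disk = (sub_y - y0) ** 2 + (sub_x - x0) ** 2 <= r * r
            disk &= mask[y_lo:y_hi, x_lo:x_hi]  # nuclei stay inside the tissue
            blue[y_lo:y_hi, x_lo:x_hi][disk] = config.nucleus_intensity
    blue = blue + rng.normal(0, config.noise_sd, (h, w))
    rgb[:, :, 2] = blue

    return np.clip(rgb, 0.0, 1.0), mask
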