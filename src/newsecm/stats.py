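"""Differential statistics for censored label-free proteomics data.

The stages mirror the standard Perseus-style workflow for intensity tables
with missing-not-at-random dropout:

1. log2 transform (zeros become missing),
2. QRILC imputation — per sample, the complete-data mean and standard
   deviation are estimated by quantile regression of the observed lower tail
   against standard-normal quantiles, and missing cells are drawn from a
   normal truncated above at the estimated censoring point,
3. two-tailed Welch t-tests with Satterthwaite degrees of freedom,
4. permutation-based FDR: the null distribution of |t| is built by permuting
   group labels (exhaustively when feasible), and per-protein q values are
   the minimum estimated FDR at which the protein is called, enforced
   monotone in p,
5. fold changes as ratios of geometric means (log2 FC = difference of mean
   log2 intensities), and volcano classification at |log2 FC| > 1, q < 0.05
   with boundary values non-significant.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri

from .io import ProteinQuantTable

VOLCANO_HIGH_A = "high-in-A"
VOLCANO_HIGH_B = "high-in-B"
VOLCANO_NS = "NS"


# ---------------------------------------------------------------------------
# log2 matrix with explicit missingness


@dataclass
class Log2Matrix:
    """Proteins x samples log2 intensities with an explicit missing mask.

    ``values`` stores NaN where the protein was not observed; ``imputed``
    flags cells that were filled in by imputation (never True for cells that
    were observed).
    """

    values: pd.DataFrame
    imputed: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.imputed.shape:
            raise ValueError("values and imputed flags must share a shape")
        if bool((self.imputed & self.values.isna()).any().any()):
            raise ValueError("imputed cells must carry values")

    @property
    def missing(self) -> pd.DataFrame:
        return self.values.isna()

    def n_imputed(self, samples: Sequence[str]) -> pd.Series:
        return self.imputed.loc[:, list(samples)].sum(axis=1)

    def copy(self) -> "Log2Matrix":
        return Log2Matrix(self.values.copy(), self.imputed.copy())


def log2_transform(table: ProteinQuantTable) -> Log2Matrix:
    """log2 of positive intensities; zeros become missing (NaN)."""
    intens = table.intensities
    arr = intens.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logged = np.log2(arr, out=np.full_like(arr, np.nan), where=arr > 0)
    values = pd.DataFrame(logged, index=intens.index, columns=intens.columns)
    flags = pd.DataFrame(False, index=intens.index, columns=intens.columns)
    return Log2Matrix(values, flags)


# ---------------------------------------------------------------------------
# QRILC imputation


@dataclass(frozen=True)
class QrilcParams:
    """Tuning for quantile-regression imputation of left-censored data.

    ``fit_quantiles`` is the observed-quantile range used for the
    regression; ``tune`` shifts the truncation point down by ``tune`` x the
    estimated sd (a small safety margin against imputing at the censoring
    boundary); ``min_observed`` is the minimum number of observed values a
    sample needs for a stable fit.
    """

    fit_quantiles: tuple[float, float] = (0.001, 0.5)
    tune: float = 0.001
    min_observed: int = 20
    n_fit_points: int = 100

    def __post_init__(self) -> None:
        lo, hi = self.fit_quantiles
        if not (0 <= lo < hi <= 1):
            raise ValueError("fit_quantiles must satisfy 0 <= lo < hi <= 1")


@dataclass
class QrilcFit:
    """Per-sample estimates: complete-data (mu, sigma) and truncation point."""

    mu: pd.Series
    sigma: pd.Series
    cutoff: pd.Series


def _fit_censored_normal(
    observed: np.ndarray, n_missing: int, params: QrilcParams
) -> tuple[float, float, float]:
    """Estimate (mu, sigma, cutoff) of the complete distribution.

    With a fraction ``pi`` of the lowest values censored, the observed
    empirical quantile at level u corresponds to the complete-distribution
    quantile at pi + u * (1 - pi); regressing observed quantiles on the
    matching standard-normal quantiles recovers (mu, sigma).
    """
    n_obs = len(observed)
    pi = n_missing / (n_obs + n_missing)
    lo, hi = params.fit_quantiles
    u = np.linspace(lo, hi, params.n_fit_points)
    q_obs = np.quantile(observed, u)
    z = ndtri(pi + u * (1.0 - pi))
    slope, intercept = np.polyfit(z, q_obs, 1)
    sigma = max(float(slope), 1e-12)
    mu = float(intercept)
    pi_eff = max(pi, 1e-6)
    cutoff = mu + sigma * (float(ndtri(pi_eff)) - params.tune)
    return mu, sigma, cutoff


def qrilc_impute(
    matrix: Log2Matrix,
    params: QrilcParams | None = None,
    seed: int | np.random.Generator | None = None,
    return_fit: bool = False,
):
    """Fill missing log2 values by draws from an upper-truncated normal.

    Per sample: estimate the complete-data (mu, sigma) by quantile
    regression on the observed values, then draw each missing cell from
    N(mu, sigma^2) truncated above at the estimated censoring point.  A
    matrix without missing cells is returned unchanged.  Seeded and
    reproducible.
    """
    params = params or QrilcParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = matrix.values.copy()
    flags = matrix.imputed.copy()
    mus, sigmas, cutoffs = {}, {}, {}
    for sample in values.columns:
        col = values[sample]
        missing = col.isna()
        observed = col[~missing].to_numpy()
        if len(observed) < params.min_observed:
            raise ValueError(
                f"sample {sample!r} has only {len(observed)} observed values "
                f"(minimum {params.min_observed}); filter sparse samples or rows first"
            )
        if not missing.any():
            mus[sample], sigmas[sample], cutoffs[sample] = (
                float(np.mean(observed)),
                float(np.std(observed, ddof=1)),
                np.nan,
            )
            continue
        mu, sigma, cutoff = _fit_censored_normal(observed, int(missing.sum()), params)
        b = (cutoff - mu) / sigma
        draws = sps.truncnorm.rvs(
            -np.inf, b, loc=mu, scale=sigma, size=int(missing.sum()), random_state=rng
        )
        values.loc[missing, sample] = draws
        flags.loc[missing, sample] = True
        mus[sample], sigmas[sample], cutoffs[sample] = mu, sigma, cutoff
    out = Log2Matrix(values, flags)
    if return_fit:
        fit = QrilcFit(
            pd.Series(mus, name="mu"),
            pd.Series(sigmas, name="sigma"),
            pd.Series(cutoffs, name="cutoff"),
        )
        return out, fit
    return out


# ---------------------------------------------------------------------------
# Welch t


def _welch_t_groups(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t over rows of two (proteins x samples) blocks.

    NaN cells are treated as missing (pairwise-complete); rows with fewer
    than 2 observed values in either group get t = df = p = NaN.
    Degenerate rows (zero variance in both groups) follow the convention
    t = 0, p = 1 for equal means and |t| = inf, p = 0 otherwise.
    """
    obs_a, obs_b = ~np.isnan(a), ~np.isnan(b)
    na = obs_a.sum(axis=1).astype(float)
    nb = obs_b.sum(axis=1).astype(float)
    valid = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        va, vb = np.nanvar(a, axis=1, ddof=1), np.nanvar(b, axis=1, ddof=1)
        se2 = va / na + vb / nb
        diff = ma - mb
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = valid & (se2 == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(degenerate, na + nb - 2, df)
    t = np.where(valid, t, np.nan)
    df = np.where(valid, df, np.nan)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(degenerate & (t == 0), 1.0, p)
    p = np.where(valid, p, np.nan)
    return t, df, p


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed Welch t-test: returns (t, Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t-test needs at least 2 values per group")
    t, df, p = _welch_t_groups(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t-test (one-sample t on differences).

    Zero-variance differences: t = 0, p = 1 when all differences are zero;
    otherwise |t| = inf, p = 0 (a constant nonzero shift).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired t-test requires equal-length vectors")
    if len(before) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = after - before
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# permutation FDR


@dataclass
class PermutationFdrResult:
    t: pd.Series
    p: pd.Series
    q: pd.Series
    n_permutations: int
    exhaustive: bool


def _label_assignments(
    n: int, n_a: int, max_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Group-A index sets: all C(n, n_a) when feasible, else a seeded subset.

    The observed assignment (indices 0..n_a-1) is always included, matching
    the convention that permutation p values count the identity.
    """
    total = math.comb(n, n_a)
    if total <= max_permutations:
        sets = np.array(list(itertools.combinations(range(n), n_a)), dtype=int)
        return sets, True
    picks = [tuple(range(n_a))]
    seen = {picks[0]}
    while len(picks) < max_permutations:
        draw = tuple(sorted(rng.choice(n, size=n_a, replace=False).tolist()))
        if draw not in seen:
            seen.add(draw)
            picks.append(draw)
    return np.array(picks, dtype=int), False


def permutation_fdr(
    values: pd.DataFrame | np.ndarray,
    labels_a: Sequence[bool],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationFdrResult:
    """Perseus-style permutation FDR for a two-group comparison.

    For every protein the observed Welch |t| is compared against the pooled
    null |t| distribution obtained by reassigning group labels (all distinct
    assignments when their number is <= ``n_permutations``, else a seeded
    random subset).  q(protein) = (mean permutation count of null |t| >=
    |t_obs|) / (observed count of |t| >= |t_obs|), made monotone
    non-decreasing in p and clipped to [0, 1].
    """
    if isinstance(values, pd.DataFrame):
        index = values.index
        mat = values.to_numpy(dtype=float)
    else:
        mat = np.asarray(values, dtype=float)
        if mat.ndim == 1:
            mat = mat[None, :]
        index = pd.RangeIndex(mat.shape[0])
    labels_a = np.asarray(labels_a, dtype=bool)
    if labels_a.shape[0] != mat.shape[1]:
        raise ValueError("labels length must equal the number of samples")
    n_a = int(labels_a.sum())
    n = mat.shape[1]
    if n_a < 2 or n - n_a < 2:
        raise ValueError("both groups need at least 2 samples")
    if math.comb(n, n_a) < 2:
        raise ValueError("fewer than 2 distinct label permutations")

    rng = np.random.default_rng(seed)
    # order columns so the observed assignment is indices 0..n_a-1
    order = np.concatenate([np.flatnonzero(labels_a), np.flatnonzero(~labels_a)])
    mat = mat[:, order]
    assignments, exhaustive = _label_assignments(n, n_a, n_permutations, rng)

    t_obs, _, p_obs = _welch_t_groups(mat[:, :n_a], mat[:, n_a:])
    abs_obs = np.abs(t_obs)
    if np.isnan(abs_obs).any():
        raise ValueError(
            "some proteins have fewer than 2 observed values per group; "
            "apply the detection prefilter (or imputation) first"
        )

    all_idx = np.arange(n)
    null_abs = np.empty((len(assignments), mat.shape[0]))
    for k, idx_a in enumerate(assignments):
        idx_b = np.setdiff1d(all_idx, idx_a, assume_unique=True)
        t_k, _, _ = _welch_t_groups(mat[:, idx_a], mat[:, idx_b])
        null_abs[k] = np.abs(t_k)
    n_perm = len(assignments)

    flat = null_abs.ravel()
    null_sorted = np.sort(flat[~np.isnan(flat)])
    # mean null count with |t| >= threshold, per observed threshold
    exceed = len(null_sorted) - np.searchsorted(null_sorted, abs_obs, side="left")
    false_pos = exceed / n_perm
    # observed positives at each protein's own threshold
    obs_sorted = np.sort(abs_obs)
    positives = len(abs_obs) - np.searchsorted(obs_sorted, abs_obs, side="left")
    fdr = false_pos / positives
    # step-down: q(i) = min FDR over proteins at least as insignificant,
    # which enforces monotone non-decreasing q along increasing p
    order_p = np.argsort(p_obs, kind="stable")
    q = np.empty_like(fdr)
    q[order_p] = np.minimum.accumulate(fdr[order_p][::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)

    return PermutationFdrResult(
        t=pd.Series(t_obs, index=index, name="t"),
        p=pd.Series(p_obs, index=index, name="p"),
        q=pd.Series(q, index=index, name="q"),
        n_permutations=n_perm,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# fold changes and volcano classification


def geometric_fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """FC = geomean(A) / geomean(B) on decimal (positive) intensities.

    log2(FC) equals mean(log2 A) - mean(log2 B); imputed log2 values may be
    exponentiated first with no effect on the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("geometric fold change requires strictly positive intensities")
    return float(2.0 ** (np.mean(np.log2(a)) - np.mean(np.log2(b))))


def classify_volcano(
    log2fc: float, q: float, fc_threshold: float = 1.0, q_threshold: float = 0.05
) -> str:
    """Volcano category with boundary values counted as non-significant.

    high-in-A iff log2fc > fc_threshold and q < q_threshold; high-in-B iff
    log2fc < -fc_threshold and q < q_threshold; everything else (including
    log2fc = +-threshold or q = q_threshold exactly) is NS.
    """
    if q < q_threshold and log2fc > fc_threshold:
        return VOLCANO_HIGH_A
    if q < q_threshold and log2fc < -fc_threshold:
        return VOLCANO_HIGH_B
    return VOLCANO_NS


def p_cutoff_for_q(
    p_values: Sequence[float], q_values: Sequence[float], q_threshold: float = 0.05
) -> float | None:
    """Position of the plotted p cut-off line: max p among proteins with q < threshold."""
    p = np.asarray(p_values, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q vectors must have the same length")
    passing = p[q < q_threshold]
    if len(passing) == 0:
        return None
    return float(passing.max())


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n_overlap: pd.DataFrame


def correlation_matrix(
    values: pd.DataFrame, min_overlap: int = 3
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between sample columns.

    ``values`` is a log2 matrix with NaN marking missing cells.  Pairs with
    fewer than ``min_overlap`` shared observed proteins are flagged with NaN
    rather than raising.  p values come from the t-transform of r.
    """
    cols = list(values.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n_ov = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    arr = values.to_numpy(dtype=float)
    finite = np.isfinite(arr)
    for i in range(k):
        n_ov.iloc[i, i] = int(finite[:, i].sum())
    for i in range(k):
        for j in range(i + 1, k):
            both = finite[:, i] & finite[:, j]
            n = int(both.sum())
            n_ov.iloc[i, j] = n_ov.iloc[j, i] = n
            if n < min_overlap:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            rij, pij = sps.pearsonr(arr[both, i], arr[both, j])
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return CorrelationMatrix(r=r, p=p, n_overlap=n_ov)
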