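"""Total-intensity normalization, detection prefilter, Grubbs outlier test.

Normalization follows the total-ion-style scheme used for label-free
proteomics: within a group *K* of samples, the intensity of protein *X* in
sample *i* becomes

    X_Ki,normalized = X_Ki,original * Sum_average / Sum_Ki

where ``Sum_Ki`` is sample *i*'s total intensity and ``Sum_average`` is the
arithmetic mean of the totals over the group.  After normalization every
sample total in a group equals the group's pre-normalization average total;
the transform is idempotent and invariant to rescaling single samples.

Groups are defined by sample-metadata fields, which covers the three schemes
used in practice: per treatment group (each (model, treatment) arm averaged
separately), across all selected samples (one group), and across all input
samples (one group on an input-only table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinQuantTable


@dataclass(frozen=True)
class NormalizationScheme:
    """How samples are grouped for total-intensity normalization.

    ``group_by`` lists the sample-metadata fields whose joint values define a
    group; the empty tuple places every sample in one group.
    """

    mode: str
    group_by: tuple[str, ...]

    @classmethod
    def within_treatment_groups(cls) -> "NormalizationScheme":
        """One group per (model, treatment) arm (per-arm averages)."""
        return cls("within-group", ("model", "treatment"))

    @classmethod
    def across_selected(cls) -> "NormalizationScheme":
        """All samples of the table normalized together."""
        return cls("across-selected-samples", ())

    @classmethod
    def all_samples(cls) -> "NormalizationScheme":
        """Alias for one group over the whole table (input-wide scheme)."""
        return cls("all-samples", ())

    @classmethod
    def from_mode(cls, mode: str) -> "NormalizationScheme":
        table = {
            "within-group": cls.within_treatment_groups,
            "across-selected-samples": cls.across_selected,
            "all-samples": cls.all_samples,
        }
        if mode not in table:
            raise ValueError(f"unknown normalization mode {mode!r}; choose from {sorted(table)}")
        return table[mode]()


def _sample_groups(table: ProteinQuantTable, scheme: NormalizationScheme) -> list[list[str]]:
    if not scheme.group_by:
        return [list(table.intensities.columns)]
    meta = table.samples.loc[list(table.intensities.columns), list(scheme.group_by)]
    groups = []
    for _, sub in meta.groupby(list(scheme.group_by), sort=False):
        groups.append(list(sub.index))
    return groups


def total_intensity_normalize(
    table: ProteinQuantTable, scheme: NormalizationScheme
) -> ProteinQuantTable:
    """Scale each sample by (group-average total) / (sample total).

    Zeros stay zero.  Raises if any sample total is zero (the scale factor
    would be undefined).
    """
    totals = table.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total samples cannot be normalized: {list(zero.index)}")
    scaled = table.intensities.copy()
    for group in _sample_groups(table, scheme):
        group_totals = totals.loc[group]
        factors = group_totals.mean() / group_totals
        scaled.loc[:, group] = scaled.loc[:, group] * factors
    return table.with_intensities(scaled)


def prefilter_min_nonzero(
    table: ProteinQuantTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    k: int = 2,
) -> tuple[ProteinQuantTable, ProteinQuantTable]:
    """Split proteins into statistically testable vs qualitative-only.

    ``testable`` holds proteins with at least ``k`` nonzero values in *both*
    comparison groups (a numerical p value can be assigned); ``qualitative``
    holds the remainder, which is retained for group-mean bar summaries
    rather than silently dropped.
    """
    group_a, group_b = list(group_a), list(group_b)
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < k:
            raise ValueError(
                f"comparison group {name} has {len(grp)} samples, fewer than k={k}"
            )
    nz_a = (table.intensities.loc[:, group_a] > 0).sum(axis=1)
    nz_b = (table.intensities.loc[:, group_b] > 0).sum(axis=1)
    testable_mask = (nz_a >= k) & (nz_b >= k)
    testable = table.select_proteins(table.intensities.index[testable_mask])
    qualitative = table.select_proteins(table.intensities.index[~testable_mask])
    return testable, qualitative


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-Grubbs critical value at level ``alpha``.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with
    t = t_{1-alpha/(2n), n-2}.
    """
    if n < 3:
        raise ValueError("Grubbs's test requires at least 3 values")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_outliers(
    values: Sequence[float], alpha: float = 0.05, iterate: bool = False
) -> list[int]:
    """Indices of outliers by the two-sided single-outlier Grubbs test.

    One pass flags at most the single most extreme value (ties broken to the
    lower index); ``iterate=True`` repeats on the remaining values until no
    rejection.  A zero standard deviation flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Grubbs's test requires a 1-d sample with n >= 3")
    remaining = list(range(len(x)))
    flagged: list[int] = []
    while len(remaining) >= 3:
        sub = x[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        g = dev.max() / sd
        if g <= grubbs_critical_value(len(sub), alpha):
            break
        flagged.append(remaining.pop(int(np.argmax(dev))))
        if not iterate:
            break
    return flagged
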