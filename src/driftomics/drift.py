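"""Omics drift: per-feature log-ratios to a young reference and their spread.

The drift of feature *i* in sample *s* is ``md = log(x_is / x̄_i,ref)``,
the log-ratio of the sample's level to the feature's mean in the
reference (young) group. The variance of the pooled md values of a group
quantifies how far that group has drifted from the reference; comparing
this spread between groups (Brown-Forsythe test) asks whether aging
dysregulates the ome and whether a treatment suppresses the
dysregulation.

For transcriptome drift, lowly expressed features (reference mean below
a percentile cutoff, 20th by default) are removed first, and the grand
mean of all drift values is set to zero so that library-depth offsets do
not inflate the variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DriftOptions",
    "DriftResult",
    "GroupDrift",
    "compute_drift",
    "drift_variance",
    "brown_forsythe",
]

logger = logging.getLogger(__name__)

_LOG_BASES = {"e": np.e, "natural": np.e, 2: 2.0, "2": 2.0, 10: 10.0, "10": 10.0}


@dataclass(frozen=True)
class DriftOptions:
    reference_group: str = "young"
    low_expression_percentile: float = 0.20
    center_mean_to_zero: bool = True
    log_base: float | str = "e"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_expression_percentile < 1.0:
            raise ValueError("low_expression_percentile must lie in [0, 1)")
        if self.log_base not in _LOG_BASES:
            raise ValueError(f"log_base must be one of {sorted(map(str, _LOG_BASES))}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


@dataclass
class DriftResult:
    drift: pd.DataFrame  # retained features x samples
    per_sample_variance: pd.Series
    per_group_pooled: dict[str, np.ndarray]
    excluded_features: frozenset[str]
    options: DriftOptions
    groups: pd.Series = field(repr=False)  # sample -> group


class GroupDrift(NamedTuple):
    pooled: dict[str, np.ndarray]
    variance: pd.Series


def _group_map(metadata: pd.DataFrame) -> pd.Series:
    return pd.Series(
        metadata["group"].to_numpy(), index=metadata["sample"].to_numpy()
    )


def compute_drift(
    matrix: pd.DataFrame, metadata: pd.DataFrame, opts: DriftOptions | None = None
) -> DriftResult:
    """Drift matrix md(feature, sample) relative to the reference-group mean.

    Features whose reference mean is non-positive after the pseudocount,
    or falls below the ``low_expression_percentile`` quantile of
    reference means, are excluded.
    """
    opts = opts or DriftOptions()
    groups = _group_map(metadata)
    samples = [s for s in matrix.columns if s in groups.index]
    if len(samples) != matrix.shape[1]:
        missing = sorted(set(matrix.columns) - set(groups.index))
        raise ValueError(f"samples absent from metadata: {missing}")
    ref_samples = [s for s in samples if groups[s] == opts.reference_group]
    if len(ref_samples) < 2:
        raise ValueError(
            f"reference group {opts.reference_group!r} needs >=2 samples, "
            f"found {len(ref_samples)}"
        )

    x = matrix.astype(float) + opts.pseudocount
    ref_mean = x[ref_samples].mean(axis=1)

    excluded = set(ref_mean.index[ref_mean <= 0])
    if excluded:
        logger.info("excluding %d features with non-positive reference mean", len(excluded))
    positive = ref_mean[ref_mean > 0]
    if opts.low_expression_percentile > 0:
        cutoff = positive.quantile(opts.low_expression_percentile)
        low = set(positive.index[positive < cutoff])
        logger.info("excluding %d features below the %.0fth reference percentile",
                    len(low), 100 * opts.low_expression_percentile)
        excluded |= low
    keep = [f for f in matrix.index if f not in excluded]
    if not keep:
        raise ValueError("no features retained for drift")

    base = _LOG_BASES[opts.log_base]
    md = np.log(x.loc[keep].div(ref_mean.loc[keep], axis=0)) / np.log(base)
    if opts.center_mean_to_zero:
        md = md - float(md.to_numpy().mean())

    pooled = {
        g: md[[s for s in samples if groups[s] == g]].to_numpy().ravel()
        for g in pd.unique(groups.loc[samples])
    }
    return DriftResult(
        drift=md,
        per_sample_variance=md.var(axis=0, ddof=1),
        per_group_pooled=pooled,
        excluded_features=frozenset(excluded),
        options=opts,
        groups=groups.loc[samples],
    )


def drift_variance(
    result: DriftResult, feature_subset: Iterable[str] | None = None
) -> GroupDrift:
    """Pooled per-group drift values and their sample variance.

    ``feature_subset=None`` reproduces the whole-ome pooled values; a
    subset (e.g. a Mitocarta-style gene list) restricts the drift matrix
    before pooling.
    """
    if feature_subset is None:
        pooled = {g: v.copy() for g, v in result.per_group_pooled.items()}
    else:
        subset = list(dict.fromkeys(feature_subset))
        present = [f for f in subset if f in result.drift.index]
        if not present:
            raise KeyError(
                f"no subset features retained in drift matrix; missing: {subset[:10]}"
            )
        sub = result.drift.loc[present]
        groups = result.groups
        pooled = {
            g: sub[[s for s in sub.columns if groups[s] == g]].to_numpy().ravel()
            for g in pd.unique(groups)
        }
    variance = pd.Series(
        {g: float(np.var(v, ddof=1)) for g, v in pooled.items()}, name="drift_variance"
    )
    return GroupDrift(pooled=pooled, variance=variance)


def brown_forsythe(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brown-Forsythe test of equal spread (Levene with median centers).

    One-way ANOVA on absolute deviations from each group's median.
    Returns ``(F, p)``; degenerate all-equal deviations give ``(0, 1)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    z = [np.abs(a - np.median(a)) for a in arrays]
    flat = np.concatenate(z)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    stat, p = stats.levene(*arrays, center="median")
    return float(stat), float(p)
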