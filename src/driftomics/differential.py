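"""Differential genes and metabolites, and signature comparisons.

Genes: CPM-based expression filtering, TMM between-sample normalization,
Welch t-tests on normalized log2-CPM, Benjamini-Hochberg FDR, and the
significance rule FDR < 0.05 with |log2FC| > 0.3 (strict inequalities).

Metabolites: minimum-value imputation of missing entries, a generalized
log (glog) transform, Welch t-tests on the glog scale with BH FDR (no
fold threshold), fold changes reported on the raw scale.

The Welch test on normalized log-CPM is a deliberate, documented
simplification of a count GLM: this package's contribution is the
thresholding/drift/network layer, not dispersion modelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_expressed",
    "tmm_factors",
    "de_genes",
    "bh_fdr",
    "impute_min",
    "glog_transform",
    "de_metabolites",
    "compare_signatures",
    "SignatureComparison",
]

logger = logging.getLogger(__name__)


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0).astype(float)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    return counts / lib * 1e6


def filter_expressed(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep genes with CPM strictly above ``min_cpm`` in at least
    ``ceil(min_fraction * n_samples)`` samples."""
    cpm = _cpm(counts)
    need = math.ceil(min_fraction * counts.shape[1])
    keep = (cpm > min_cpm).sum(axis=1) >= need
    return counts.loc[keep]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Two-sample TMM factor: doubly trimmed, precision-weighted mean of
    M-values, following the published trimmed-mean-of-M-values recipe."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0:
        raise ValueError("sample shares no usable genes with the reference")
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = math.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep) or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the column whose 75th percentile of
    library-scaled counts is closest to the mean of those percentiles.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >=2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("samples with zero total counts")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, k], x[:, ref_idx], lib[k], lib[ref_idx], trim_m, trim_a)
            for k in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def bh_fdr(pvals: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; zero-variance rows with equal
    means get p = 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def _group_columns(metadata: pd.DataFrame, group: str) -> list[str]:
    cols = metadata.loc[metadata["group"] == group, "sample"].tolist()
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    return cols


def _assemble(
    index: pd.Index,
    log2fc: np.ndarray,
    p: np.ndarray,
    significant: np.ndarray,
    contrast: tuple[str, str],
    fdr: np.ndarray,
) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
            "significant": significant,
            "contrast": f"{contrast[0]} vs {contrast[1]}",
        },
        index=index,
    )
    out.index.name = "feature_id"
    return out


def de_genes(
    counts: pd.DataFrame,
    factors: pd.Series,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.3,
) -> pd.DataFrame:
    """Differential genes for ``contrast = (test, reference)``.

    log2FC is the mean normalized log2(CPM+1) difference (test minus
    reference); p from row-wise Welch tests; significance requires
    fdr < ``fdr_threshold`` and |log2fc| > ``lfc_threshold``, both strict.
    """
    lib = counts.sum(axis=0).astype(float)
    eff_lib = lib * factors.reindex(counts.columns)
    logcpm = np.log2(counts / eff_lib * 1e6 + 1.0)
    cols_a = _group_columns(metadata, contrast[0])
    cols_b = _group_columns(metadata, contrast[1])
    a = logcpm[cols_a].to_numpy()
    b = logcpm[cols_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p = _welch_rows(a, b)
    fdr = bh_fdr(p)
    sig = (fdr < fdr_threshold) & (np.abs(log2fc) > lfc_threshold)
    return _assemble(counts.index, log2fc, p, sig, contrast, fdr)


def impute_min(metabolites: pd.DataFrame) -> pd.DataFrame:
    """Replace each metabolite's missing entries by its minimum observed
    value across all samples."""
    all_missing = metabolites.index[metabolites.isna().all(axis=1)].tolist()
    if all_missing:
        raise ValueError(f"metabolites with no observed value: {all_missing}")
    row_min = metabolites.min(axis=1, skipna=True)
    out = metabolites.copy()
    return out.apply(lambda row: row.fillna(row_min[row.name]), axis=1)


def glog_transform(
    matrix: pd.DataFrame, lam: float | str = "auto"
) -> pd.DataFrame:
    """Generalized log: glog(x) = ln((x + sqrt(x^2 + lambda^2)) / 2).

    ``lam="auto"`` uses the smallest positive observed value. Variance
    stabilizing near zero, converging to ln(x) as lambda -> 0.
    """
    if matrix.isna().any().any():
        raise ValueError("glog requires an imputed (missing-free) matrix")
    x = matrix.to_numpy(dtype=float)
    if lam == "auto":
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("no positive values to set lambda automatically")
        lam_value = float(positive.min())
    else:
        lam_value = float(lam)
    if lam_value <= 0:
        raise ValueError("lambda must be positive")
    out = np.log((x + np.sqrt(x**2 + lam_value**2)) / 2.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def de_metabolites(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    fdr_threshold: float = 0.05,
    lam: float | str = "auto",
) -> pd.DataFrame:
    """Differential metabolites for ``contrast = (test, reference)``.

    Welch t on glog-transformed abundances; the fold change is the ratio
    of raw group means (reported as log2fc); significance is
    fdr < ``fdr_threshold`` with no fold threshold.
    """
    if matrix.isna().any().any():
        raise ValueError("impute missing values first (impute_min)")
    glog = glog_transform(matrix, lam=lam)
    cols_a = _group_columns(metadata, contrast[0])
    cols_b = _group_columns(metadata, contrast[1])
    p = _welch_rows(glog[cols_a].to_numpy(), glog[cols_b].to_numpy())
    fold = matrix[cols_a].mean(axis=1) / matrix[cols_b].mean(axis=1)
    log2fc = np.log2(fold.to_numpy())
    fdr = bh_fdr(p)
    sig = fdr < fdr_threshold
    return _assemble(matrix.index, log2fc, p, sig, contrast, fdr)


@dataclass
class SignatureComparison:
    """Venn partition of two significant sets and fold-change correlations.

    Correlations are Pearson r of the two contrasts' log2 fold changes
    restricted to each partition; ``None`` where a partition has fewer
    than 3 features.
    """

    shared: frozenset[str]
    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    r_shared: float | None
    r_unique_a: float | None
    r_unique_b: float | None


def _partition_r(
    res_a: pd.DataFrame, res_b: pd.DataFrame, features: frozenset[str]
) -> float | None:
    if len(features) < 3:
        return None
    idx = sorted(features)
    r = stats.pearsonr(
        res_a.loc[idx, "log2fc"].to_numpy(), res_b.loc[idx, "log2fc"].to_numpy()
    ).statistic
    return float(r)


def compare_signatures(
    res_a: pd.DataFrame, res_b: pd.DataFrame
) -> SignatureComparison:
    """Shared/unique significant features of two contrasts, with
    fold-change correlations evaluated on both results' log2fc."""
    common = res_a.index.intersection(res_b.index)
    if len(common) == 0:
        raise ValueError("results share no feature universe")
    sig_a = frozenset(res_a.index[res_a["significant"]]) & frozenset(common)
    sig_b = frozenset(res_b.index[res_b["significant"]]) & frozenset(common)
    shared = sig_a & sig_b
    unique_a = sig_a - sig_b
    unique_b = sig_b - sig_a
    return SignatureComparison(
        shared=shared,
        unique_to_a=unique_a,
        unique_to_b=unique_b,
        r_shared=_partition_r(res_a, res_b, shared),
        r_unique_a=_partition_r(res_a, res_b, unique_a),
        r_unique_b=_partition_r(res_a, res_b, unique_b),
    )
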