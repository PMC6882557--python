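"""PCA with group confidence ellipses, and k-means expression clustering.

Transcriptome PCA operates on log2(FPKM+5) of the top-expressed genes
(top 10% by row sum of log2(FPKM+5) by default); metabolome PCA is run
on glog-transformed abundances. Group ellipses on the first two
components are multivariate-normal contours at a chosen coverage level
(70% by default), with squared radius the chi-square(2) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PcaResult",
    "Ellipse",
    "select_top_expressed",
    "pca",
    "confidence_ellipse",
    "group_ellipses",
    "zscore_rows",
    "kmeans_clusters",
    "aging_up_cluster",
]


def select_top_expressed(
    fpkm: pd.DataFrame, fraction: float = 0.10
) -> tuple[pd.DataFrame, float]:
    """Genes whose total log2(FPKM+5) over samples reaches the top
    ``fraction``; returns the subset and the realized score cutoff.

    Ties at the cutoff are all kept.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    score = np.log2(fpkm + 5.0).sum(axis=1)
    if fraction == 1.0:
        return fpkm.copy(), float(score.min())
    cutoff = float(np.quantile(score.to_numpy(), 1.0 - fraction))
    return fpkm.loc[score >= cutoff], cutoff


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_fraction: np.ndarray
    ellipses: dict[str, "Ellipse"]


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PcaResult:
    """PCA of samples (columns of a feature x sample matrix).

    Sign convention: each component's largest-magnitude loading is made
    positive, so results are reproducible across runs and libraries.
    """
    x = matrix.to_numpy(dtype=float).T  # samples as observations
    if x.shape[0] < 2:
        raise ValueError("need >=2 samples")
    if np.allclose(x, x[0]):
        raise ValueError("matrix has no variance across samples")
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance features cannot be scaled")
        x = (x - x.mean(axis=0)) / sd
    elif center:
        x = x - x.mean(axis=0)
    model = PCA(svd_solver="full")
    scores = model.fit_transform(x)
    comps = model.components_  # components x features
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] *= -1.0
            scores[:, j] *= -1.0
    names = [f"PC{j + 1}" for j in range(comps.shape[0])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=names),
        loadings=pd.DataFrame(comps.T, index=matrix.index, columns=names),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
        ellipses={},
    )


@dataclass
class Ellipse:
    """Coverage ellipse {x : (x-center)' cov^-1 (x-center) <= radius^2}."""

    center: np.ndarray
    covariance: np.ndarray
    level: float
    radius: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        m = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.covariance), d)
        return m <= self.radius**2


def confidence_ellipse(scores2d: np.ndarray, level: float = 0.70) -> Ellipse:
    """Multivariate-normal coverage ellipse of a group's 2-D scores.

    The squared radius is the chi-square quantile with 2 degrees of
    freedom at ``level`` (2.4079 at 70%).
    """
    pts = np.asarray(scores2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores2d must be n x 2")
    if pts.shape[0] < 3:
        raise ValueError("need >=3 samples for a covariance ellipse")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.det(cov) <= np.finfo(float).tiny:
        raise ValueError(
            "singular group covariance; jitter the scores or use fewer components"
        )
    return Ellipse(
        center=pts.mean(axis=0),
        covariance=cov,
        level=level,
        radius=float(np.sqrt(stats.chi2.ppf(level, df=2))),
    )


def group_ellipses(
    result: PcaResult, metadata: pd.DataFrame, level: float = 0.70
) -> dict[str, Ellipse]:
    """Per-group PC1/PC2 ellipses; stored on the result and returned."""
    groups = pd.Series(
        metadata["group"].to_numpy(), index=metadata["sample"].to_numpy()
    )
    out = {}
    for g in pd.unique(groups):
        samples = [s for s in result.scores.index if groups.get(s) == g]
        pts = result.scores.loc[samples, ["PC1", "PC2"]].to_numpy()
        out[str(g)] = confidence_ellipse(pts, level=level)
    result.ellipses = out
    return out


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scaling; zero-variance features are dropped."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > 0
    return matrix.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)


def kmeans_clusters(
    zmatrix: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """Euclidean k-means of z-scaled features; deterministic per seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > zmatrix.shape[0]:
        raise ValueError(f"k={k} exceeds {zmatrix.shape[0]} features")
    model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = model.fit_predict(zmatrix.to_numpy(dtype=float))
    return pd.Series(labels, index=zmatrix.index, name="cluster")


def aging_up_cluster(
    zmatrix: pd.DataFrame,
    labels: pd.Series,
    metadata: pd.DataFrame,
    old_group: str = "old",
    reference_group: str = "young",
) -> int:
    """Label of the cluster whose mean profile rises with aging and
    falls under treatment (highest old-minus-young plus old-minus-treated
    contrast of cluster-average z-scores)."""
    groups = pd.Series(
        metadata["group"].to_numpy(), index=metadata["sample"].to_numpy()
    )
    treated = [
        g for g in pd.unique(groups) if g not in (old_group, reference_group)
    ]
    best_label, best_score = None, -np.inf
    for label in sorted(labels.unique()):
        sub = zmatrix.loc[labels.index[labels == label]]
        group_mean = {
            g: float(sub[[s for s in sub.columns if groups.get(s) == g]].mean().mean())
            for g in pd.unique(groups)
        }
        score = group_mean[old_group] - group_mean[reference_group]
        if treated:
            score += group_mean[old_group] - float(
                np.mean([group_mean[t] for t in treated])
            )
        if score > best_score:
            best_label, best_score = int(label), score
    assert best_label is not None
    return best_label
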