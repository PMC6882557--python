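"""Metabolite-set enrichment scores and Fisher overlap tests.

The enrichment score of a set is the ratio of ratios

    score = (k / m) / (K / M)

with k significant members detected in the set, m detected members of
the set, K significant features overall and M detected features overall
("altered/detected" relative to the background rate). An upper-tail
hypergeometric p-value P(X >= k) is attached for ranking stability; the
score itself is the primary display quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from scipy.stats.contingency import odds_ratio

__all__ = ["EnrichmentRecord", "metabolite_set_enrichment", "fisher_overlap"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    k: int  # significant members detected in the set
    m: int  # detected members of the set
    K: int  # significant features overall
    M: int  # detected features overall
    score: float
    p: float


def metabolite_set_enrichment(
    significant: Iterable[str],
    detected: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    min_set_size: int = 2,
) -> list[EnrichmentRecord]:
    """Enrichment of each feature set among significant features.

    Sets are intersected with ``detected`` before counting; sets with
    fewer than ``min_set_size`` detected members are skipped. Records
    are sorted by decreasing score, ties broken by p-value.
    """
    detected_set = set(detected)
    significant_set = set(significant)
    if not significant_set <= detected_set:
        extra = sorted(significant_set - detected_set)[:10]
        raise ValueError(f"significant features not among detected: {extra}")
    big_m = len(detected_set)
    big_k = len(significant_set)
    if big_k == 0:
        raise ValueError("no significant features; enrichment undefined")
    records = []
    for name, members in sets.items():
        in_set = set(members) & detected_set
        m = len(in_set)
        if m < min_set_size:
            logger.info("skipping set %r with %d detected members", name, m)
            continue
        k = len(in_set & significant_set)
        score = (k / m) / (big_k / big_m)
        p = float(stats.hypergeom.sf(k - 1, big_m, big_k, m))
        records.append(EnrichmentRecord(name, k, m, big_k, big_m, score, p))
    records.sort(key=lambda r: (-r.score, r.p, r.set_name))
    return records


def fisher_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test of overlap between two feature sets.

    Returns the conditional maximum-likelihood odds ratio and the exact
    p-value of the 2x2 membership table over ``universe``.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a = set(set_a) & u
    b = set(set_b) & u
    n_ab = len(a & b)
    n_a = len(a - b)
    n_b = len(b - a)
    n_rest = len(u) - n_ab - n_a - n_b
    table = [[n_ab, n_a], [n_b, n_rest]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    oratio = float(odds_ratio(table, kind="conditional").statistic)
    return oratio, p
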