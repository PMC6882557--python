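"""Synthetic multi-omics data with known ground truth.

Emulates a four-group aging-intervention design (a young reference group,
an aged group, and aged groups receiving one of two treatments): bulk
RNA-seq count matrices with a planted fraction of age-shifted genes,
metabolite abundance tables with a handful of large planted folds and
missing-at-low-abundance entries, and a metabolite-reaction network with
an active module planted around a hub metabolite (acetyl-CoA by default).

Treatment groups receive the aging shifts attenuated by a per-treatment
suppression factor on the log scale: suppression 1 restores the young
mean exactly, 0 leaves the aged shift untouched.

All draws come from seeded, stream-separated generators so that every
artefact (and the ground truth linking them) is reproducible from the
configuration alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_metadata",
    "generate_transcriptome",
    "generate_metabolome",
    "generate_network",
    "generate_metabolite_sets",
    "generate_dataset",
    "group_mean_matrix",
]

REFERENCE_GROUP = "young"
DEFAULT_HUB = "acetyl-CoA"

#: Largest aging fold changes reported for TCA-cycle metabolites
#: (old/young ratios), plus the 2-fold drop of the acetyl-CoA hub.
DEFAULT_FOLD_TABLE: dict[str, float] = {
    "alpha-ketoglutarate": 9.51,
    "succinate": 7.85,
    "citrate": 6.19,
    "aconitate": 5.73,
    "acetyl-CoA": 0.5,
}


def _default_group_sizes() -> dict[str, int]:
    return {"young": 6, "old": 6, "old+A": 6, "old+B": 6}


def _default_suppression() -> dict[str, float]:
    return {"old+A": 0.9, "old+B": 0.5}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: four groups of n=6, a
    moderate fraction of age-shifted genes with log2 fold changes of
    spread ``aging_log2fc_sd``, strong suppression under treatment A and
    partial suppression under treatment B, and the named metabolite
    folds of :data:`DEFAULT_FOLD_TABLE`.
    """

    n_genes: int = 2000
    n_metabolites: int = 50
    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    frac_aging_genes: float = 0.05
    aging_log2fc_sd: float = 0.8
    suppression: Mapping[str, float] = field(default_factory=_default_suppression)
    metabolite_fold_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLD_TABLE)
    )
    missing_rate_low_abundance: float = 0.3
    metabolite_cv: float = 0.2
    dispersion: float = 0.05
    hub_metabolite: str = DEFAULT_HUB
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_metabolites < 1:
            raise ValueError("n_genes and n_metabolites must be positive")
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} has degenerate size {n}")
        if REFERENCE_GROUP not in self.group_sizes:
            raise ValueError(f"design must include a {REFERENCE_GROUP!r} group")
        for name, frac in [
            ("frac_aging_genes", self.frac_aging_genes),
            ("missing_rate_low_abundance", self.missing_rate_low_abundance),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        for t, s in self.suppression.items():
            if t not in self.group_sizes:
                raise ValueError(f"suppression names unknown group {t!r}")
            if t == REFERENCE_GROUP:
                raise ValueError("the reference group cannot be treated")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"suppression for {t!r} must lie in [0, 1]")
        for m, fold in self.metabolite_fold_table.items():
            if fold <= 0:
                raise ValueError(f"fold for {m!r} must be > 0, got {fold}")
        if len(self.metabolite_fold_table) > self.n_metabolites:
            raise ValueError(
                "planted module larger than n_metabolites: "
                f"{len(self.metabolite_fold_table)} named metabolites "
                f"vs n_metabolites={self.n_metabolites}"
            )
        if self.aging_log2fc_sd <= 0 or self.dispersion < 0 or self.metabolite_cv <= 0:
            raise ValueError("spread/noise parameters must be positive")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects behind one synthetic dataset."""

    affected_gene_ids: frozenset[str]
    gene_log2fc: pd.Series  # old vs young, all genes (0 where unaffected)
    suppression: dict[str, float]
    metabolite_log2fc: pd.Series  # old vs young, all metabolites
    planted_module_nodes: frozenset[str]


@dataclass
class _Plan:
    gene_ids: list[str]
    base_gene_mean: np.ndarray
    gene_log2fc: np.ndarray
    affected_idx: np.ndarray
    met_ids: list[str]
    base_met_level: np.ndarray
    met_log2fc: np.ndarray
    module_nodes: list[str]  # hub first
    module_edge_genes: list[str]


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _plan(config: SynthConfig) -> _Plan:
    """Deterministic planted-effect layout shared by all generators."""
    rng = _rng(config, 0)
    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    base = np.exp(rng.normal(np.log(80.0), 1.2, config.n_genes))

    n_aff = round(config.frac_aging_genes * config.n_genes)
    if config.frac_aging_genes > 0 and n_aff < 1:
        warnings.warn("frac_aging_genes too small for n_genes; no genes affected")
    affected = np.sort(rng.choice(config.n_genes, size=n_aff, replace=False))
    lfc = np.zeros(config.n_genes)
    lfc[affected] = rng.normal(0.0, config.aging_log2fc_sd, n_aff)

    named = list(config.metabolite_fold_table)
    met_ids = named + [
        f"met_{i:04d}" for i in range(config.n_metabolites - len(named))
    ]
    base_met = np.exp(rng.uniform(np.log(1e3), np.log(1e6), config.n_metabolites))
    met_lfc = np.zeros(config.n_metabolites)
    for j, m in enumerate(named):
        met_lfc[j] = np.log2(config.metabolite_fold_table[m])

    hub = config.hub_metabolite if config.hub_metabolite in named else (
        named[0] if named else None
    )
    module = ([hub] + [m for m in named if m != hub]) if hub else []

    # Enzyme genes on the planted module's edges: the most strongly
    # age-shifted genes, so metabolite and gene evidence co-localize.
    order = affected[np.argsort(-np.abs(lfc[affected]))]
    n_edges = max(len(module) - 1, 0)
    if len(order) and n_edges:
        edge_genes = [gene_ids[order[i % len(order)]] for i in range(n_edges)]
    else:
        edge_genes = []
    return _Plan(
        gene_ids, base, lfc, affected, met_ids, base_met, met_lfc, module, edge_genes
    )


def _group_effect(config: SynthConfig, group: str) -> float:
    """Fraction of the full aging shift expressed in ``group``."""
    if group == REFERENCE_GROUP:
        return 0.0
    return 1.0 - float(config.suppression.get(group, 0.0))


def generate_metadata(config: SynthConfig) -> pd.DataFrame:
    """Sample-to-group table: columns ``sample`` and ``group``."""
    records = [
        {"sample": f"{g}_{i + 1}", "group": g}
        for g, n in config.group_sizes.items()
        for i in range(n)
    ]
    return pd.DataFrame.from_records(records, columns=["sample", "group"])


def _sample_effects(config: SynthConfig, metadata: pd.DataFrame) -> np.ndarray:
    return np.array([_group_effect(config, g) for g in metadata["group"]])


def group_mean_matrix(config: SynthConfig) -> pd.DataFrame:
    """Noise-free expected counts, genes x groups."""
    plan = _plan(config)
    cols = {}
    for g in config.group_sizes:
        eff = _group_effect(config, g)
        cols[g] = plan.base_gene_mean * 2.0 ** (plan.gene_log2fc * eff)
    return pd.DataFrame(cols, index=plan.gene_ids)


def _truth(config: SynthConfig, plan: _Plan) -> GroundTruth:
    return GroundTruth(
        affected_gene_ids=frozenset(plan.gene_ids[i] for i in plan.affected_idx),
        gene_log2fc=pd.Series(plan.gene_log2fc, index=plan.gene_ids, name="log2fc"),
        suppression={t: float(s) for t, s in config.suppression.items()},
        metabolite_log2fc=pd.Series(
            plan.met_log2fc, index=plan.met_ids, name="log2fc"
        ),
        planted_module_nodes=frozenset(plan.module_nodes),
    )


def generate_transcriptome(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Counts and FPKM tables (genes x samples) plus the ground truth.

    Counts follow a negative-binomial (gamma-Poisson) model around the
    group mean; FPKM assumes unit (1 kb) gene lengths, so values are
    library-size-scaled relative abundances.
    """
    plan = _plan(config)
    metadata = generate_metadata(config)
    rng = _rng(config, 1)
    eff = _sample_effects(config, metadata)
    mu = plan.base_gene_mean[:, None] * 2.0 ** (plan.gene_log2fc[:, None] * eff[None, :])
    if config.dispersion > 0:
        lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    counts = pd.DataFrame(counts, index=plan.gene_ids, columns=metadata["sample"])
    lib = counts.sum(axis=0).astype(float)
    fpkm = counts / lib * 1e6  # 1 kb lengths: FPKM == CPM
    return counts, fpkm, _truth(config, plan)


def generate_metabolome(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Metabolite x sample abundances with missing-at-low-abundance gaps.

    Abundances are log-normal around the group mean with coefficient of
    variation ``metabolite_cv``; entries below a metabolite's 10th
    percentile go missing with probability
    ``missing_rate_low_abundance``.
    """
    plan = _plan(config)
    metadata = generate_metadata(config)
    rng = _rng(config, 2)
    eff = _sample_effects(config, metadata)
    sigma = np.sqrt(np.log1p(config.metabolite_cv**2))
    log_mu = (
        np.log(plan.base_met_level)[:, None]
        + np.log(2.0) * plan.met_log2fc[:, None] * eff[None, :]
    )
    values = np.exp(log_mu + rng.normal(0.0, sigma, log_mu.shape))
    if config.missing_rate_low_abundance > 0:
        q10 = np.quantile(values, 0.10, axis=1, keepdims=True)
        drop = (values < q10) & (
            rng.random(values.shape) < config.missing_rate_low_abundance
        )
        values = np.where(drop, np.nan, values)
    table = pd.DataFrame(values, index=plan.met_ids, columns=metadata["sample"])
    return table, _truth(config, plan)


@dataclass
class MetabolicNetwork:
    """Undirected metabolite graph; each edge carries enzyme gene ids.

    Thin wrapper over a :class:`networkx.Graph` whose edges have a
    non-empty ``genes`` tuple attribute.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            genes = data.get("genes", ())
            if not genes:
                raise ValueError(f"edge {u!r}-{v!r} has no annotated genes")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_triples(self) -> list[tuple[str, str, tuple[str, ...]]]:
        return [
            (u, v, tuple(d["genes"])) for u, v, d in self.graph.edges(data=True)
        ]


def generate_network(config: SynthConfig) -> tuple[MetabolicNetwork, GroundTruth]:
    """Connected metabolite network with the planted module around the hub.

    The planted module is a star of the hub metabolite and the other
    named fold-table metabolites; its edges are annotated with the most
    strongly age-shifted genes. The remaining metabolites attach through
    a random tree plus extra random edges, annotated with genes sampled
    outside the module's enzyme set.
    """
    plan = _plan(config)
    rng = _rng(config, 3)
    g = nx.Graph()
    g.add_nodes_from(plan.met_ids)

    module_gene_set = set(plan.module_edge_genes)
    background_pool = [gi for gi in plan.gene_ids if gi not in module_gene_set]

    def background_genes() -> tuple[str, ...]:
        k = int(rng.integers(1, 3))
        return tuple(rng.choice(background_pool, size=k, replace=False))

    if plan.module_nodes:
        hub = plan.module_nodes[0]
        for i, nb in enumerate(plan.module_nodes[1:]):
            genes = (
                (plan.module_edge_genes[i],)
                if i < len(plan.module_edge_genes)
                else background_genes()
            )
            g.add_edge(hub, nb, genes=genes)

    # Background metabolites join through a random tree anchored at the
    # module periphery (never the hub) and extra edges stay among the
    # background, so the hub's degree is set by the planted star alone
    # and capture under identifier shuffling reflects chance, not
    # topological centrality.
    anchors = plan.module_nodes[1:] or plan.met_ids[:1]
    remaining = [m for m in plan.met_ids if m not in plan.module_nodes]
    if not plan.module_nodes:
        remaining = [m for m in remaining if m != plan.met_ids[0]]
    placed_background: list[str] = []
    for node in rng.permutation(remaining):
        if placed_background:
            anchor = placed_background[int(rng.integers(len(placed_background)))]
        else:
            anchor = anchors[int(rng.integers(len(anchors)))]
        g.add_edge(str(node), anchor, genes=background_genes())
        placed_background.append(str(node))

    n_extra = round(0.3 * len(placed_background))
    attempts = 0
    while n_extra > 0 and len(placed_background) >= 2 and attempts < 20 * config.n_metabolites:
        attempts += 1
        u, v = rng.choice(placed_background, size=2, replace=False)
        if g.has_edge(u, v):
            continue
        g.add_edge(str(u), str(v), genes=background_genes())
        n_extra -= 1

    return MetabolicNetwork(g), _truth(config, plan)


def generate_metabolite_sets(
    config: SynthConfig, n_random_sets: int = 5, set_size: int = 8
) -> dict[str, set[str]]:
    """Toy metabolite sets: the planted module plus random sets."""
    plan = _plan(config)
    rng = _rng(config, 4)
    sets: dict[str, set[str]] = {}
    if plan.module_nodes:
        sets["planted_module"] = set(plan.module_nodes)
    size = min(set_size, config.n_metabolites)
    for i in range(n_random_sets):
        members = rng.choice(plan.met_ids, size=size, replace=False)
        sets[f"random_set_{i + 1}"] = set(str(m) for m in members)
    return sets


@dataclass
class SyntheticDataset:
    """Bundle of all synthetic artefacts for one configuration."""

    config: SynthConfig
    metadata: pd.DataFrame
    counts: pd.DataFrame
    fpkm: pd.DataFrame
    metabolites: pd.DataFrame
    network: MetabolicNetwork
    metabolite_sets: dict[str, set[str]]
    truth: GroundTruth


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    metadata = generate_metadata(config)
    counts, fpkm, truth = generate_transcriptome(config)
    metabolites, _ = generate_metabolome(config)
    network, _ = generate_network(config)
    sets = generate_metabolite_sets(config)
    return SyntheticDataset(
        config, metadata, counts, fpkm, metabolites, network, sets, truth
    )
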