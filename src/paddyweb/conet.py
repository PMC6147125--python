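"""Family-level co-occurrence networks from abundance time series.

Taxon count tables are aggregated to family level (taxa without a
family assignment are dropped), rare families (< 0.5 permille of total
reads by default) are discarded, and all pairwise Spearman rank
correlations across the samples of one temperature are computed.  An
edge connects two families when the correlation is strong and positive
(0.6 <= rho <= 0.9 by default) and significant after Benjamini-Hochberg
FDR correction (q < 0.01).  The resulting network is partitioned into
modules by greedy modularity maximisation (or seeded Louvain), and
per-module abundance time courses summarise which part of the food web
each module represents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from paddyweb.errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
FAMILY_DEPTH = 5  # lineage fields required for a family assignment


@dataclass
class AbundanceTable:
    """Taxon x sample counts with lineage and sample metadata.

    ``counts``: DataFrame, rows = taxon ids, columns = sample ids,
    non-negative integers.  ``lineage``: taxon id -> semicolon-joined
    lineage string (domain;phylum;class;order;family[;genus]).
    ``metadata``: DataFrame indexed by sample id with columns ``day``,
    ``temperature_C``, ``replicate``.
    """

    counts: pd.DataFrame
    lineage: Mapping[str, str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in counts table")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"samples lacking metadata: {sorted(missing)}")
        for col in ("day", "temperature_C", "replicate"):
            if col not in self.metadata.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        if self.metadata.loc[list(self.counts.columns)].duplicated(
            subset=["day", "temperature_C", "replicate"]
        ).any():
            raise ValidationError("duplicate (day, temperature, replicate) metadata")

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions over the retained taxa (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValidationError(f"samples with zero total counts: {empty}")
        return self.counts / totals

    def select_temperature(self, temperature_C: float) -> "AbundanceTable":
        """Restrict to the samples of one incubation temperature."""
        keep = self.metadata.index[self.metadata["temperature_C"] == temperature_C]
        keep = [s for s in self.counts.columns if s in set(keep)]
        if not keep:
            raise ValidationError(f"no samples at {temperature_C} degC")
        return AbundanceTable(self.counts[keep], self.lineage, self.metadata.loc[keep])


def family_of(lineage: str) -> str | None:
    """Extract the family rank from a semicolon lineage, or None."""
    fields = [f.strip() for f in lineage.split(";")]
    if len(fields) >= FAMILY_DEPTH and fields[FAMILY_DEPTH - 1]:
        return fields[FAMILY_DEPTH - 1]
    return None


def aggregate_families(table: AbundanceTable) -> AbundanceTable:
    """Sum counts of taxa sharing a family; drop unassigned taxa.

    Mirrors the retention rule that only OTUs classified to family
    level enter the network analysis.
    """
    families: dict[str, str] = {}
    for taxon in table.counts.index:
        lineage = table.lineage.get(taxon)
        if lineage is None:
            raise ConfigurationError(f"taxon {taxon!r} missing from lineage map")
        fam = family_of(lineage)
        if fam is not None:
            families[taxon] = fam
    if not families:
        raise ValidationError("no taxa with family-level assignment")
    kept = table.counts.loc[list(families)]
    n_dropped = len(table.counts) - len(kept)
    logger.info("family aggregation: %d taxa kept, %d dropped", len(kept), n_dropped)
    agg = kept.groupby(pd.Series(families), sort=True).sum()
    agg.index.name = "family"
    fam_lineage = {}
    for taxon, fam in families.items():
        fields = [f.strip() for f in table.lineage[taxon].split(";")]
        fam_lineage.setdefault(fam, ";".join(fields[:FAMILY_DEPTH]))
    return AbundanceTable(agg, fam_lineage, table.metadata)


def prevalence_filter(table: AbundanceTable, threshold: float = 5e-4) -> AbundanceTable:
    """Keep families holding at least ``threshold`` of all reads.

    The default 5e-4 is the 0.5 permille cutoff; "less than" is strict,
    so a family exactly at the threshold is retained.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"prevalence threshold must lie in (0, 1), got {threshold}")
    grand_total = table.counts.values.sum()
    if grand_total == 0:
        raise ValidationError("table has zero total counts")
    fractions = table.counts.sum(axis=1) / grand_total
    keep = fractions.index[fractions >= threshold]
    if len(keep) == 0:
        raise ValidationError("prevalence filter removed every family")
    logger.info("prevalence filter %.2g: %d of %d families retained",
                threshold, len(keep), len(table.counts))
    return AbundanceTable(
        table.counts.loc[keep],
        {f: table.lineage[f] for f in keep if f in table.lineage},
        table.metadata,
    )


@dataclass
class CorrelationMatrices:
    """All-pairs Spearman rho with raw and FDR-adjusted p-values."""

    families: list[str]
    rho: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_samples: int


def _spearman_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-distribution approximation, n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return p


def replicate_mean_view(relab: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Average the sample columns of one temperature over replicates.

    Returns one column per day (n = number of days).  Offered as an
    alternative correlation input where replicate scatter should not
    count as signal; note the resulting n is usually too small for the
    default p-value approximation to be trustworthy.
    """
    days = metadata.loc[list(relab.columns), "day"]
    out = relab.T.groupby(days.values).mean().T
    out.columns = [f"d{d:g}" for d in out.columns]
    return out


def spearman_all_pairs(
    relab: pd.DataFrame,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> CorrelationMatrices:
    """Spearman correlation of every family pair across samples.

    ``relab`` has families as rows and samples as columns (typically the
    relative-abundance view restricted to one temperature).  rho is the
    Pearson correlation of mid-ranks (average ranks on ties).  With
    ``method="t"`` (default) p comes from the t approximation with n-2
    degrees of freedom; ``method="permutation"`` uses a seeded
    Monte-Carlo permutation null (two-sided, add-one corrected), which
    is preferable for small n.  A family with constant abundance has
    undefined rho, recorded as rho=0, p=1.
    """
    n = relab.shape[1]
    if n < 4:
        raise ValidationError(f"need at least 4 samples for correlations, got {n}")
    if relab.shape[0] < 2:
        raise ValidationError("need at least 2 families")
    if method not in ("t", "permutation"):
        raise ValidationError(f"unknown p-value method {method!r}")
    families = list(relab.index)
    ranks = stats.rankdata(relab.values, axis=1)
    constant = ranks.std(axis=1) == 0
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.asarray(rho, dtype=float)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)

    if method == "t":
        p = _spearman_pvalue(rho, n)
    else:
        p = _spearman_permutation_pvalue(ranks, rho, n_permutations, seed)
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(len(families), k=1)
    q_flat = bh_fdr(p[iu])
    q = np.zeros_like(p)
    q[iu] = q_flat
    q = q + q.T
    return CorrelationMatrices(families=families, rho=rho, p=p, q=q, n_samples=n)


def _spearman_permutation_pvalue(
    ranks: np.ndarray, rho: np.ndarray, n_permutations: int, seed: int
) -> np.ndarray:
    """Two-sided Monte-Carlo permutation p for all pairs at once.

    One shared set of column permutations is applied to the second
    member of every pair; p = (1 + #{|rho_perm| >= |rho|}) / (B + 1).
    """
    k, n = ranks.shape
    sd = ranks.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (ranks - ranks.mean(axis=1, keepdims=True)) / (sd[:, None] * np.sqrt(n))
    rng = np.random.default_rng(seed)
    exceed = np.zeros((k, k))
    abs_rho = np.abs(rho)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        rho_perm = z @ z[:, perm].T
        exceed += np.abs(rho_perm) >= abs_rho - 1e-12
    p = (1.0 + exceed) / (n_permutations + 1.0)
    # symmetrise: the shared-permutation trick is not symmetric in i, j
    return np.minimum(p, p.T)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CoNetwork:
    """Co-occurrence graph with node metadata and (optionally) modules.

    Node attributes: ``mean_abundance``, ``degree``, ``module``.
    Edge attributes: ``rho``, ``q``.
    """

    graph: nx.Graph
    rho_min: float
    rho_max: float
    alpha: float
    modularity_score: float | None = None
    algorithm: str | None = None
    seed: int | None = None

    @property
    def modules(self) -> dict[str, int]:
        return {n: d["module"] for n, d in self.graph.nodes(data=True) if "module" in d}


def build_network(
    corr: CorrelationMatrices,
    rho_min: float = 0.6,
    rho_max: float = 0.9,
    alpha: float = 0.01,
    abundances: Mapping[str, float] | None = None,
) -> CoNetwork:
    """Threshold the correlation matrices into a co-occurrence graph.

    An edge requires rho_min <= rho <= rho_max (inclusive window; only
    positive correlations are eligible) and q < alpha (strict).
    Families failing every test stay in the graph as isolated nodes.
    """
    if not (0 < rho_min <= rho_max <= 1):
        raise ValidationError("require 0 < rho_min <= rho_max <= 1")
    g = nx.Graph()
    for fam in corr.families:
        mean_ab = float(abundances.get(fam, np.nan)) if abundances is not None else np.nan
        g.add_node(fam, mean_abundance=mean_ab)
    k = len(corr.families)
    for i in range(k):
        for j in range(i + 1, k):
            rho = corr.rho[i, j]
            q = corr.q[i, j]
            if rho_min <= rho <= rho_max and q < alpha:
                g.add_edge(corr.families[i], corr.families[j], rho=float(rho), q=float(q))
    for fam in g.nodes:
        g.nodes[fam]["degree"] = g.degree[fam]
    logger.info("network: %d nodes, %d edges (rho in [%g, %g], q < %g)",
                g.number_of_nodes(), g.number_of_edges(), rho_min, rho_max, alpha)
    return CoNetwork(graph=g, rho_min=rho_min, rho_max=rho_max, alpha=alpha)


def modularity(graph: nx.Graph, partition: Mapping[str, int]) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2), unweighted edges."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    communities: dict[int, set] = {}
    for node, label in partition.items():
        communities.setdefault(label, set()).add(node)
    q = 0.0
    for members in communities.values():
        internal = sum(1 for u, v in graph.edges(members) if u in members and v in members)
        degree_sum = sum(graph.degree[n] for n in members)
        q += internal / m - (degree_sum / (2.0 * m)) ** 2
    return q


def _greedy_partition(graph: nx.Graph) -> dict[str, int]:
    """Deterministic greedy agglomerative modularity maximisation.

    Start from singletons and repeatedly merge the connected community
    pair with the largest modularity gain, all the way down to a single
    community; the best partition along the merge path is kept and then
    polished by a deterministic single-node move pass.  Ties are broken
    by the lexicographically smallest pair of community labels (a
    community is labelled by its smallest member node).
    """
    m = graph.number_of_edges()
    nodes = sorted(graph.nodes)
    if m == 0:
        return {n: i for i, n in enumerate(nodes)}
    tol = 1e-12
    # community label -> members; label is the smallest member node
    comm: dict[str, set] = {n: {n} for n in nodes}
    # fraction of edge endpoints per community
    a = {n: graph.degree[n] / (2.0 * m) for n in nodes}
    # e[frozenset({x, y})] = fraction of edges between communities x, y
    e: dict[frozenset, float] = {}
    for u, v in graph.edges:
        if u == v:
            continue
        key = frozenset((u, v))
        e[key] = e.get(key, 0.0) + 1.0 / m

    q = modularity(graph, {n: i for i, n in enumerate(nodes)})
    best_q, best_comm = q, [set(s) for s in comm.values()]
    while len(comm) > 1:
        best_gain = -math.inf
        best_pair: tuple[str, str] | None = None
        for key, e_ab in e.items():
            x, y = sorted(key)
            # merging x and y changes Q by e_xy - 2 a_x a_y
            gain = e_ab - 2.0 * a[x] * a[y]
            if gain > best_gain + tol:
                best_gain, best_pair = gain, (x, y)
            elif abs(gain - best_gain) <= tol and best_pair is not None and (x, y) < best_pair:
                best_pair = (x, y)
        if best_pair is None:
            break  # remaining communities are disconnected from each other
        x, y = best_pair
        comm[x] |= comm.pop(y)
        a[x] = a[x] + a.pop(y)
        new_e: dict[frozenset, float] = {}
        for key, val in e.items():
            mapped = frozenset(x if lbl == y else lbl for lbl in key)
            if len(mapped) == 2:
                new_e[mapped] = new_e.get(mapped, 0.0) + val
        e = new_e
        q += best_gain
        if q > best_q + tol:
            best_q, best_comm = q, [set(s) for s in comm.values()]

    partition = {n: idx for idx, members in enumerate(best_comm) for n in members}
    return _refine_partition(graph, partition)


def _refine_partition(graph: nx.Graph, partition: dict[str, int]) -> dict[str, int]:
    """Deterministic single-node move polish: repeatedly relocate the
    node whose move (to an adjacent or new community) yields the largest
    modularity gain, until no positive move remains."""
    m = graph.number_of_edges()
    if m == 0:
        return partition
    part = dict(partition)
    tol = 1e-12
    deg = dict(graph.degree)
    two_m = 2.0 * m
    for _ in range(10 * len(part) + 10):
        # degree sums per community
        sigma: dict[int, float] = {}
        for n, c in part.items():
            sigma[c] = sigma.get(c, 0.0) + deg[n]
        best_gain, best_move = tol, None
        for n in sorted(part):
            c_old = part[n]
            links: dict[int, int] = {}
            for nb in graph.neighbors(n):
                if nb != n:
                    links[part[nb]] = links.get(part[nb], 0) + 1
            k_in_old = links.get(c_old, 0)
            free = min(set(range(len(part) + 1)) - set(sigma))
            for c_new in sorted(set(links) | {free}):
                if c_new == c_old:
                    continue
                gain = (links.get(c_new, 0) - k_in_old) / m + deg[n] * (
                    sigma[c_old] - deg[n] - sigma.get(c_new, 0.0)
                ) / (two_m * m)
                if gain > best_gain + tol or (
                    abs(gain - best_gain) <= tol
                    and best_move is not None
                    and (n, c_new) < best_move
                ):
                    best_gain, best_move = max(gain, best_gain), (n, c_new)
        if best_move is None:
            break
        n, c_new = best_move
        part[n] = c_new
    return part


def _louvain_partition(graph: nx.Graph, seed: int) -> dict[str, int]:
    """Louvain via python-igraph with a recorded seed."""
    import igraph as ig
    import random as _random

    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    _random.seed(seed)
    ig.set_random_number_generator(_random)
    clustering = g.community_multilevel()
    return {nodes[i]: int(clustering.membership[i]) for i in range(len(nodes))}


def partition_modules(
    net: CoNetwork, algorithm: str = "greedy", seed: int = 0
) -> CoNetwork:
    """Assign module ids and the modularity score to a network.

    ``greedy`` is the deterministic default; ``louvain`` runs igraph's
    multilevel algorithm with the given seed.  Isolated nodes become
    singleton modules.  Module ids are re-labelled by decreasing size
    (ties by smallest member) so the output is stable.
    """
    if algorithm == "greedy":
        partition = _greedy_partition(net.graph)
    elif algorithm == "louvain":
        partition = _louvain_partition(net.graph, seed)
    else:
        raise ValidationError(f"unknown partition algorithm {algorithm!r}")
    communities: dict[int, set] = {}
    for n, lbl in partition.items():
        communities.setdefault(lbl, set()).add(n)
    ordered = sorted(communities.values(), key=lambda s: (-len(s), min(s)))
    relabel = {n: idx for idx, members in enumerate(ordered) for n in members}
    for n in net.graph.nodes:
        net.graph.nodes[n]["module"] = relabel[n]
    net.modularity_score = modularity(net.graph, relabel)
    net.algorithm = algorithm
    net.seed = seed
    logger.info("partition (%s): %d modules, Q = %.4f",
                algorithm, len(ordered), net.modularity_score)
    return net


def node_degrees(net: CoNetwork) -> dict[str, int]:
    """Family -> number of incident edges."""
    return {n: int(net.graph.degree[n]) for n in net.graph.nodes}


def module_profiles(
    net: CoNetwork,
    table: AbundanceTable,
    min_family_fraction: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-module relative-abundance time courses.

    For each module and day: the summed relative abundance of member
    families, averaged over replicates (+/- SE).  Also returns a
    per-family breakdown restricted to families whose overall mean
    relative abundance exceeds ``min_family_fraction`` (the "dominant
    families" view).
    """
    modules = net.modules
    if not modules:
        raise ValidationError("network has no module partition; run partition_modules first")
    missing = set(modules) - set(table.counts.index)
    if missing:
        raise ValidationError(f"families in network absent from table: {sorted(missing)}")
    relab = table.relative_abundance()
    meta = table.metadata.loc[list(relab.columns)]

    long = relab.stack().rename("abundance").reset_index()
    long.columns = ["family", "sample", "abundance"]
    long["day"] = meta.loc[long["sample"], "day"].values
    long["module"] = long["family"].map(modules)
    member = long.dropna(subset=["module"]).copy()
    member["module"] = member["module"].astype(int)

    per_sample = member.groupby(["module", "day", "sample"], sort=True)["abundance"].sum()
    module_series = (
        per_sample.groupby(["module", "day"])
        .agg(
            mean_abundance="mean",
            se_abundance=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
        )
        .reset_index()
    )

    overall_mean = relab.mean(axis=1)
    dominant = overall_mean.index[overall_mean > min_family_fraction]
    fam_rows = member[member["family"].isin(dominant)]
    family_series = (
        fam_rows.groupby(["module", "family", "day"], sort=True)["abundance"]
        .agg(
            mean_abundance="mean",
            se_abundance=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
        )
        .reset_index()
    )
    return module_series, family_series
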