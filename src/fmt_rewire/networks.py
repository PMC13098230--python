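"""Typed (ternary) Spearman correlation networks and edge persistence.

Nodes are clinical markers, taxa, or metabolites; an undirected edge is kept
when the tie-aware Spearman coefficient satisfies |rho| > 0.6 and p < 0.05
(the conventional cutoffs for genus co-abundance networks, both
configurable). Taxon features are prevalence-filtered (>= 60% of samples)
before testing. Clinical-clinical pairs are excluded from testing by default
because clinical indices are mutually dependent by construction.

"Rewiring" between a baseline and a post-treatment network is quantified as
edge persistence: the fraction of baseline edges (after excluding
metabolite-metabolite pairs) whose unordered node pair recurs in the post
network, by default with matching correlation sign. Edge p-values are not
multiplicity-adjusted (the p < 0.05 edge rule is per-pair); a BH option is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

from .containers import FeatureTable
from .screening import bh_adjust, prevalence_filter

DEFAULT_RHO_THRESHOLD = 0.6
DEFAULT_ALPHA = 0.05
MET_MET = frozenset({"metabolite"})  # unordered class pair {metabolite, metabolite}
CLIN_CLIN = frozenset({"clinical"})

EXACT_N_MAX = 7


def class_pair(class_a: str, class_b: str) -> frozenset:
    """Unordered class-pair key, e.g. ``frozenset({'taxon', 'metabolite'})``."""
    return frozenset({class_a, class_b})


def pair_label(pair: frozenset) -> str:
    items = sorted(pair)
    return f"{items[0]}-{items[0]}" if len(items) == 1 else f"{items[0]}-{items[1]}"


def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for small n (enumerates all n! orders)."""
    n = x_ranks.size
    xc = x_ranks - x_ranks.mean()
    denom_x = np.sqrt((xc**2).sum())
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        yp = y_ranks[list(perm)]
        yc = yp - yp.mean()
        denom = denom_x * np.sqrt((yc**2).sum())
        r = float((xc * yc).sum() / denom)
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def spearman(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rho with two-sided p.

    rho is the Pearson correlation of mid-ranks. p uses the t approximation
    with n-2 degrees of freedom for n > 7 and exact permutation enumeration
    for n <= 7. Constant input raises a ``ValueError`` (undefined
    correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N_MAX:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class TypedNetwork:
    """Node-typed undirected correlation graph.

    Thin wrapper over :class:`networkx.Graph`; node attribute ``node_class``,
    edge attributes ``rho``, ``p``, ``sign``.
    """

    graph: nx.Graph
    context: str = "baseline"
    cohort: str = "UC"
    skipped_constant: list[str] = field(default_factory=list)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def edge_class_pair(self, a: str, b: str) -> frozenset:
        return class_pair(self.graph.nodes[a]["node_class"], self.graph.nodes[b]["node_class"])

    def edge_sign(self, a: str, b: str) -> str:
        return self.graph.edges[a, b]["sign"]


def build_network(
    tables: list[FeatureTable],
    samples,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_prevalence: float = 0.6,
    context: str = "baseline",
    cohort: str = "UC",
    include_clinical_clinical: bool = False,
    adjust_edge_p: bool = False,
) -> TypedNetwork:
    """Build a typed Spearman network over the shared sample set.

    All unordered feature pairs across and within classes are tested, except
    clinical-clinical pairs (unless ``include_clinical_clinical``). Taxon
    tables are prevalence-filtered first. An edge is kept iff
    |rho| > ``rho_threshold`` and p < ``alpha`` (BH-adjusted across all
    tested pairs when ``adjust_edge_p``).
    """
    samples = list(samples)
    if len(samples) < 4:
        raise ValueError("need at least 4 shared samples")

    cols: list[tuple[str, str, np.ndarray]] = []  # (feature id, class, values)
    for tbl in tables:
        sub = tbl.subset_samples(samples)
        if tbl.feature_class == "taxon" and 0 < min_prevalence <= 1:
            sub = prevalence_filter(sub, min_prevalence)
        for fid in sub.feature_ids:
            cols.append((fid, tbl.feature_class, sub.values[fid].to_numpy(dtype=float)))

    ids = [c[0] for c in cols]
    if len(ids) != len(set(ids)):
        raise ValueError("feature ids must be unique across tables")

    g = nx.Graph()
    skipped: list[str] = []
    keep: list[int] = []
    for i, (fid, fclass, v) in enumerate(cols):
        if np.ptp(v) == 0:
            skipped.append(fid)
            continue
        g.add_node(fid, node_class=fclass)
        keep.append(i)

    n = len(samples)
    ranks = np.array([stats.rankdata(cols[i][2]) for i in keep])
    classes = [cols[i][1] for i in keep]
    kept_ids = [cols[i][0] for i in keep]

    if ranks.shape[0] >= 2:
        corr = np.corrcoef(ranks)
        cand = []
        for i in range(len(keep)):
            for j in range(i + 1, len(keep)):
                if not include_clinical_clinical and classes[i] == classes[j] == "clinical":
                    continue
                rho = float(corr[i, j])
                if n <= EXACT_N_MAX:
                    p = _spearman_exact_p(ranks[i], ranks[j], rho)
                elif abs(rho) >= 1.0:
                    p = 0.0
                else:
                    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
                    p = float(2 * stats.t.sf(abs(t), df=n - 2))
                cand.append((i, j, rho, p))
        pvals = np.array([c[3] for c in cand]) if cand else np.empty(0)
        if adjust_edge_p and pvals.size:
            pvals = bh_adjust(pvals)
        for (i, j, rho, _), p in zip(cand, pvals):
            if abs(rho) > rho_threshold and p < alpha:
                g.add_edge(
                    kept_ids[i],
                    kept_ids[j],
                    rho=rho,
                    p=float(p),
                    sign="positive" if rho > 0 else "negative",
                )
    return TypedNetwork(g, context=context, cohort=cohort, skipped_constant=skipped)


def count_class_pairs(
    net: TypedNetwork, exclude: set[frozenset] | None = None
) -> dict[str, int]:
    """Census of edges by unordered class pair.

    Returns per-pair counts plus ``total`` and ``total_after_exclusion``
    (default exclusion: metabolite-metabolite pairs).
    """
    if exclude is None:
        exclude = {MET_MET}
    census: dict[str, int] = {}
    total = 0
    excluded = 0
    for a, b in net.graph.edges:
        pair = net.edge_class_pair(a, b)
        census[pair_label(pair)] = census.get(pair_label(pair), 0) + 1
        total += 1
        if pair in exclude:
            excluded += 1
    census["total"] = total
    census["total_after_exclusion"] = total - excluded
    return census


@dataclass
class PersistenceResult:
    fraction: float  # NaN when undefined (no baseline edges after exclusion)
    persisting: set[tuple[str, str]]
    baseline_only: set[tuple[str, str]]
    post_only: set[tuple[str, str]]

    @property
    def defined(self) -> bool:
        return not np.isnan(self.fraction)


def edge_persistence(
    net_baseline: TypedNetwork,
    net_post: TypedNetwork,
    require_sign_match: bool = True,
    exclude: set[frozenset] | None = None,
) -> PersistenceResult:
    """Fraction of baseline edges whose node pair recurs post-treatment.

    The class-pair exclusion (default metabolite-metabolite) is applied
    symmetrically to both networks before matching. With
    ``require_sign_match`` a recurring pair only counts when the correlation
    sign is preserved.
    """
    if exclude is None:
        exclude = {MET_MET}

    def eligible(net: TypedNetwork) -> dict[tuple[str, str], str]:
        return {
            (a, b): net.edge_sign(a, b)
            for a, b in net.edges
            if net.edge_class_pair(a, b) not in exclude
        }

    base = eligible(net_baseline)
    post = eligible(net_post)
    persisting = {
        pair
        for pair, sign in base.items()
        if pair in post and (not require_sign_match or post[pair] == sign)
    }
    baseline_only = set(base) - persisting
    post_only = set(post) - set(base)
    fraction = len(persisting) / len(base) if base else float("nan")
    return PersistenceResult(fraction, persisting, baseline_only, post_only)


def export_network(net: TypedNetwork, path, format: str = "graphml") -> None:
    """Write a network as GraphML or an edge-list TSV.

    GraphML carries ``node_class`` and edge ``rho``/``p``/``sign``
    attributes; the TSV has columns a, a_class, b, b_class, rho, p, sign.
    """
    if format == "graphml":
        g = net.graph.copy()
        g.graph["context"] = net.context
        g.graph["cohort"] = net.cohort
        nx.write_graphml(g, path)
    elif format == "edgelist-tsv":
        rows = []
        for a, b in net.edges:
            e = net.graph.edges[a, b]
            rows.append(
                {
                    "a": a,
                    "a_class": net.graph.nodes[a]["node_class"],
                    "b": b,
                    "b_class": net.graph.nodes[b]["node_class"],
                    "rho": e["rho"],
                    "p": e["p"],
                    "sign": e["sign"],
                }
            )
        pd.DataFrame(rows, columns=["a", "a_class", "b", "b_class", "rho", "p", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_graphml(path) -> TypedNetwork:
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    return TypedNetwork(
        g, context=g.graph.get("context", "baseline"), cohort=g.graph.get("cohort", "UC")
    )


def load_edgelist_tsv(path) -> TypedNetwork:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, r in df.iterrows():
        g.add_node(r["a"], node_class=r["a_class"])
        g.add_node(r["b"], node_class=r["b_class"])
        g.add_edge(r["a"], r["b"], rho=float(r["rho"]), p=float(r["p"]), sign=r["sign"])
    return TypedNetwork(g)
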