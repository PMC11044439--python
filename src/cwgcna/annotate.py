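"""Network-structure-aware gene-set annotation of modules.

Classical over-representation only asks which genes sit in a module. Here the
module's edges carry the information: each within-module gene pair (edge)
inherits the *intersection* of its two genes' term sets, and a term's score
is the sum of the weights (TOM by default) of the edges carrying it. Two
tests are provided:

* edge-weight shuffling — the weight vector is randomly permuted over the
  module's edges (term assignments fixed) many times; the empirical p is the
  add-one upper-tail probability of the observed term weight;
* edge hypergeometric — the count of module edges carrying a term against a
  background edge population.

A plain gene-level hypergeometric over-representation test is included for
comparison with node-only enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSetCollection
from .diffstats import bh_adjust
from .network import ModuleSet

__all__ = [
    "EdgeTermMap",
    "build_edge_term_map",
    "edge_shuffle_test",
    "edge_hypergeom_test",
    "gene_hypergeom_enrich",
]


@dataclass
class EdgeTermMap:
    """Edges (i < j canonical order) with weights and a term -> edge-index map."""

    edges: list[tuple[str, str]]
    weights: np.ndarray
    term_edges: dict[str, np.ndarray]  # term id -> indices into edges

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.edges) != self.weights.size:
            raise ValueError("edges and weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be >= 0")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_edge_term_map(
    ms: ModuleSet,
    module_label: str,
    gs: GeneSetCollection,
    weight_source: str = "tom",
    min_weight: float = 0.0,
) -> EdgeTermMap:
    """All within-module feature pairs with weight >= min_weight become edges;
    each edge's terms are the intersection of its two genes' term sets.
    Genes without annotation contribute empty intersections (edges kept)."""
    if module_label not in ms.module_labels and module_label not in set(ms.assignment.values()):
        raise ValueError(f"module {module_label!r} not present")
    if ms.network is None:
        raise ValueError("module set carries no network")
    members = sorted(ms.members(module_label))
    if len(members) < 2:
        raise ValueError(f"module {module_label!r} has <2 features")
    if weight_source == "tom":
        wmat = ms.network.tom
        if wmat is None:
            raise ValueError("TOM not computed on the network")
    elif weight_source == "adjacency":
        wmat = ms.network.adjacency
    else:
        raise ValueError(f"unknown weight source {weight_source!r}")
    pos = {f: i for i, f in enumerate(ms.network.feature_ids)}
    g2t = gs.gene_to_terms()
    edges, weights = [], []
    term_edges: dict[str, list[int]] = {}
    for i, gi in enumerate(members):
        for gj in members[i + 1:]:
            w = float(wmat[pos[gi], pos[gj]])
            if w < min_weight:
                continue
            idx = len(edges)
            edges.append((gi, gj))
            weights.append(w)
            for term in g2t.get(gi, frozenset()) & g2t.get(gj, frozenset()):
                term_edges.setdefault(term, []).append(idx)
    return EdgeTermMap(edges, np.asarray(weights), {t: np.asarray(ix) for t, ix in term_edges.items()})


def edge_shuffle_test(
    etm: EdgeTermMap,
    n_shuffle: int = 1000,
    seed: int = 0,
    check_conservation: bool = False,
) -> pd.DataFrame:
    """Permutation test of per-term edge-weight sums.

    Each shuffle uniformly permutes the weight vector over all module edges;
    a term's null weight is the sum of permuted weights over its (fixed) edge
    indices. p = (1 + #{null >= observed}) / (n_shuffle + 1), BH across terms.
    The default of 1000 shuffles gives a p floor of ~1e-3.
    """
    if etm.n_edges < 2:
        raise ValueError("need >=2 edges to shuffle")
    if not etm.term_edges:
        raise ValueError("no terms mapped to any edge")
    rng = np.random.default_rng(seed)
    terms = sorted(etm.term_edges)
    observed = np.array([etm.weights[etm.term_edges[t]].sum() for t in terms])
    exceed = np.zeros(len(terms), dtype=int)
    total = etm.weights.sum()
    w = etm.weights
    for _ in range(n_shuffle):
        perm = rng.permutation(w)
        if check_conservation:
            assert abs(perm.sum() - total) < 1e-9 * max(total, 1.0)
        for k, t in enumerate(terms):
            if perm[etm.term_edges[t]].sum() >= observed[k] - 1e-12:
                exceed[k] += 1
    p = (1.0 + exceed) / (n_shuffle + 1.0)
    return pd.DataFrame({
        "term": terms,
        "n_edges": [etm.term_edges[t].size for t in terms],
        "observed_weight": observed,
        "p": p,
        "p_adj": bh_adjust(p),
    })


def combine_edge_term_maps(maps: list[EdgeTermMap]) -> EdgeTermMap:
    """Union of several edge-term maps (e.g. all modules' within-module edges),
    usable as the background population of the edge hypergeometric test."""
    if not maps:
        raise ValueError("no maps to combine")
    edges = [e for m in maps for e in m.edges]
    weights = np.concatenate([m.weights for m in maps])
    term_edges: dict[str, list[int]] = {}
    offset = 0
    for m in maps:
        for term, idx in m.term_edges.items():
            term_edges.setdefault(term, []).extend((idx + offset).tolist())
        offset += m.n_edges
    return EdgeTermMap(edges, weights, {t: np.asarray(ix) for t, ix in term_edges.items()})


def edge_hypergeom_test(etm: EdgeTermMap, background: EdgeTermMap) -> pd.DataFrame:
    """Upper-tail hypergeometric test of term edge counts vs a background.

    k = module edges carrying the term, K = background edges carrying it,
    n = module edge count, N = background edge count; p = P(X >= k). Terms
    absent from the background are skipped.
    """
    n_mod, n_bg = etm.n_edges, background.n_edges
    if n_bg < n_mod:
        raise ValueError("background must contain at least as many edges as the module")
    rows = []
    for term in sorted(set(etm.term_edges) | set(background.term_edges)):
        big_k = background.term_edges.get(term, np.empty(0)).size
        if big_k == 0:
            continue
        k = etm.term_edges.get(term, np.empty(0)).size
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_mod))
        rows.append({"term": term, "k": k, "K": big_k, "n": n_mod, "N": n_bg, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def gene_hypergeom_enrich(
    genes: set[str],
    universe: set[str],
    gs: GeneSetCollection,
) -> pd.DataFrame:
    """Standard gene-level hypergeometric over-representation (BH across terms).

    Terms disjoint from the universe are skipped; the tested gene list must be
    a non-empty subset of the universe.
    """
    genes, universe = set(genes), set(universe)
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= universe:
        raise ValueError("genes must be a subset of the universe")
    rows = []
    for tid, name, members in gs.terms:
        in_universe = members & universe
        if not in_universe:
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_universe), len(genes)))
        rows.append({"term": tid, "name": name, "k": k, "K": len(in_universe), "p": p})
    out = pd.DataFrame(rows, columns=["term", "name", "k", "K", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out
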