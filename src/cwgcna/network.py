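"""Weighted co-expression network construction and module detection.

The pipeline is the classical one: a Pearson correlation matrix is raised to
a soft-thresholding power beta to give an adjacency in [0, 1] that
approximates scale-free topology, the topological overlap matrix (TOM)
augments direct adjacency with shared-neighbour structure, features are
clustered by average-linkage hierarchical clustering on 1 - TOM, the tree is
cut at a fixed height, and each surviving module is summarised by its
eigengene — the first principal component of the module's standardized
feature submatrix.

Modules are labelled ``ME1..MEk`` in decreasing size order; ``ME0`` collects
unassigned features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datamodel import OmicsMatrix

__all__ = [
    "Network",
    "ModuleSet",
    "build_adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "compute_tom",
    "detect_modules",
    "compute_eigengenes",
    "build_modules",
]

UNASSIGNED = "ME0"


def standardize_rows(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Center and scale each row to mean 0, sd 1 (sd with ``ddof``)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant feature rows present; correlation undefined")
    return (values - mu) / sd


@dataclass
class Network:
    """Soft-thresholded adjacency plus (optionally) its TOM."""

    adjacency: np.ndarray
    soft_power: int
    signed: bool = False
    tom: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_features(self) -> int:
        return self.adjacency.shape[0]

    def connectivity(self) -> np.ndarray:
        """Node connectivity k_i = sum_{j != i} a_ij."""
        return self.adjacency.sum(axis=0) - np.diag(self.adjacency)


@dataclass
class ModuleSet:
    """Feature -> module assignment plus module eigengenes."""

    assignment: dict[str, str]
    eigengenes: pd.DataFrame  # modules x samples
    variance_explained: dict[str, float]
    network: Network | None = None

    @property
    def module_labels(self) -> list[str]:
        return list(self.eigengenes.index)

    def members(self, module: str) -> list[str]:
        return [f for f, m in self.assignment.items() if m == module]

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": list(self.assignment), "module": list(self.assignment.values())}
        )


def build_adjacency(m: OmicsMatrix, beta: int, signed: bool = False) -> Network:
    """Adjacency = |cor|^beta (unsigned) or ((1 + cor)/2)^beta (signed)."""
    if beta < 1:
        raise ValueError("beta must be a positive integer")
    x = standardize_rows(m.values)
    cor = np.corrcoef(x)
    cor = np.clip(cor, -1.0, 1.0)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return Network(a, beta, signed, feature_ids=list(m.feature_ids))


def scale_free_fit(m: OmicsMatrix, beta: int, signed: bool = False) -> tuple[float, float]:
    """Scale-free topology fit at soft power ``beta``.

    Connectivities are binned into 10 equal-width bins on log10(k);
    log10 p(k) is regressed on log10 of the bin-mean k over non-empty bins.
    Returns (R^2 of that fit, mean connectivity). The R^2 is signed: a
    positive slope (non-scale-free direction) reports 0, as does a degenerate
    fit with fewer than 3 usable bins.
    """
    if m.n_features < 20 or m.n_samples < 8:
        raise ValueError("need >=20 features and >=8 samples for a meaningful fit")
    net = build_adjacency(m, beta, signed)
    k = net.connectivity()
    mean_k = float(k.mean())
    k = k[k > 0]
    if k.size < 3:
        return 0.0, mean_k
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, 11)
    which = np.clip(np.digitize(logk, edges) - 1, 0, 9)
    xs, ys = [], []
    for b in range(10):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / logk.size))
    if len(xs) < 3:
        return 0.0, mean_k
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    r2 = float(r * r)
    if slope > 0:
        r2 = 0.0
    return r2, mean_k


def pick_soft_power(
    m: OmicsMatrix,
    candidates: list[int] | None = None,
    r2_cut: float = 0.8,
    signed: bool = False,
) -> int:
    """Smallest candidate power reaching the scale-free R^2 cut.

    Falls back (with a warning) to the argmax-R^2 candidate when none
    qualifies, e.g. on structure-free data.
    """
    candidates = sorted(candidates or range(1, 21))
    if not candidates:
        raise ValueError("no candidate powers")
    fits = [scale_free_fit(m, b, signed)[0] for b in candidates]
    for beta, r2 in zip(candidates, fits):
        if r2 >= r2_cut:
            return beta
    best = candidates[int(np.argmax(fits))]
    warnings.warn(
        f"no candidate power reached R^2 >= {r2_cut}; using argmax R^2 power {best}",
        stacklevel=2,
    )
    return best


def compute_tom(net: Network) -> Network:
    """Unsigned topological overlap: tom_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu a_uj, and unit diagonal."""
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    l = a @ a  # includes u == i/j terms only via zeroed diagonal, so already excludes them
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return Network(net.adjacency, net.soft_power, net.signed, tom=tom, feature_ids=net.feature_ids)


def detect_modules(
    net: Network,
    min_size: int = 30,
    cut_height: float = 0.9,
) -> dict[str, str]:
    """Cluster features on 1 - TOM and assign module labels.

    Average-linkage hierarchical clustering; the tree is cut at the absolute
    dissimilarity ``cut_height``; clusters below ``min_size`` fall into ME0.
    Surviving modules are renamed ME1..MEk by decreasing size, ties broken by
    the lexicographically smallest member, so labels do not depend on feature
    input order.
    """
    if net.tom is None:
        raise ValueError("TOM not computed; call compute_tom first")
    n = net.n_features
    if n < 2:
        raise ValueError("need >=2 features")
    dissim = 1.0 - net.tom
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    ids = net.feature_ids if net.feature_ids else [str(i) for i in range(n)]
    clusters: dict[int, list[str]] = {}
    for fid, c in zip(ids, raw):
        clusters.setdefault(int(c), []).append(fid)
    keep = [members for members in clusters.values() if len(members) >= min_size]
    keep.sort(key=lambda ms: (-len(ms), min(ms)))
    assignment = {fid: UNASSIGNED for fid in ids}
    for rank, members in enumerate(keep, start=1):
        for fid in members:
            assignment[fid] = f"ME{rank}"
    return assignment


def compute_eigengenes(
    m: OmicsMatrix,
    assignment: dict[str, str],
    network: Network | None = None,
) -> ModuleSet:
    """Module eigengenes: first right singular vector of each module's
    standardized submatrix, scaled to unit variance and sign-aligned so the
    eigengene correlates positively with the module's mean standardized
    profile. ``variance_explained`` is sigma_1^2 / sum sigma^2."""
    labels = sorted({mod for mod in assignment.values() if mod != UNASSIGNED},
                    key=lambda s: int(s[2:]))
    feature_pos = {f: i for i, f in enumerate(m.feature_ids)}
    eigengenes, varexp = {}, {}
    for mod in labels:
        members = [f for f, lab in assignment.items() if lab == mod]
        if len(members) < 2:
            raise ValueError(f"module {mod} has <2 features")
        sub = m.values[[feature_pos[f] for f in members]]
        sd = sub.std(axis=1, ddof=1)
        if np.any(sd == 0):
            warnings.warn(f"module {mod}: dropping zero-variance feature(s) from PC", stacklevel=2)
            sub = sub[sd > 0]
        x = standardize_rows(sub)
        # PC1 across samples = first right singular vector of the features x samples block
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        pc1 = vt[0]
        mean_profile = x.mean(axis=0)
        if np.dot(pc1, mean_profile) < 0:
            pc1 = -pc1
        pc1 = pc1 / pc1.std(ddof=1)
        eigengenes[mod] = pc1
        varexp[mod] = float(s[0] ** 2 / (s**2).sum())
    eg = pd.DataFrame(eigengenes, index=m.sample_ids).T
    return ModuleSet(dict(assignment), eg, varexp, network)


def build_modules(
    m: OmicsMatrix,
    beta: int | None = None,
    signed: bool = False,
    min_size: int = 30,
    cut_height: float = 0.9,
    r2_cut: float = 0.8,
) -> ModuleSet:
    """Convenience wrapper: power selection -> adjacency -> TOM -> modules -> eigengenes."""
    if beta is None:
        beta = pick_soft_power(m, r2_cut=r2_cut, signed=signed)
    net = compute_tom(build_adjacency(m, beta, signed))
    assignment = detect_modules(net, min_size=min_size, cut_height=cut_height)
    if all(lab == UNASSIGNED for lab in assignment.values()):
        return ModuleSet(assignment, pd.DataFrame(columns=m.sample_ids), {}, net)
    return compute_eigengenes(m, assignment, net)
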