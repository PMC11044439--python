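"""Multi-omics integration and sample clustering.

Two routes merge several feature x sample omics into one samples x components
matrix:

* CCA merge — omics are standardized, reduced pairwise by canonical
  correlation analysis (top ``n_cc`` canonical variates per block), and the
  merged matrix is folded left-to-right over the omic list: (o1, o2) ->
  merged, (merged, o3) -> merged, ... A single omic degenerates to PCA.
* WGCNA merge — each omic is decomposed into co-expression modules and
  represented by its module eigengenes; eigengene blocks are concatenated.

Sample clustering is k-means over candidate k values; the chosen k is a
2-of-3 vote of the Silhouette (max), Calinski-Harabasz (max) and
Davies-Bouldin (min) indices, with Silhouette breaking ties.

High-dimensional blocks (p >= n) make raw CCA ill-posed, so each block is
first reduced to at most n-1 whitened principal-component scores and the
canonical directions come from the SVD of the whitened cross-covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score

from .datamodel import OmicsMatrix
from .network import build_modules

__all__ = [
    "MergedRepresentation",
    "ClusterResult",
    "scale_features",
    "pairwise_cca",
    "multicca_merge",
    "wgcna_merge",
    "cluster_select_k",
]


@dataclass
class MergedRepresentation:
    """Samples x components matrix with provenance of each component block."""

    matrix: np.ndarray
    sample_ids: list[str]
    provenance: list[tuple[str, int, str]]  # (omic label, n components, method)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample ids")


@dataclass
class ClusterResult:
    labels: np.ndarray
    chosen_k: int
    indices: pd.DataFrame  # index = k; columns = silhouette, calinski, davies, valid
    per_k_labels: dict[int, np.ndarray]


def scale_features(m: OmicsMatrix) -> OmicsMatrix:
    """Standardize every feature to mean 0, sd 1; constant features dropped."""
    sd = m.values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)", stacklevel=2)
    vals = m.values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    return OmicsMatrix(vals, [f for f, k in zip(m.feature_ids, keep) if k],
                       list(m.sample_ids), m.omic_label)


def _whitened_scores(x: np.ndarray, max_rank: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whitened scores of a centered samples x p block (rank-truncated).

    Returns (scores U_r, singular values, loadings V_r) with U_r orthonormal.
    """
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = s[0] * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    r = min(int((s > tol).sum()), max_rank)
    return u[:, :r], s[:r], vt[:r]


def pairwise_cca(
    a: np.ndarray, b: np.ndarray, n_cc: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical variates of two samples x features blocks.

    Directions come from the SVD of the cross-covariance between the centered
    blocks (diagonally regularized CCA, i.e. the PLS-SVD limit), computed in
    sample space so feature counts far beyond the sample count stay cheap and
    well-posed. Fully whitened CCA is ill-posed here: when both blocks have
    rank n-1 their whitened scores span the same sample space and every
    canonical correlation is exactly 1 regardless of any shared structure.

    Returns (u, v, correlations) with the variate pairs ordered by decreasing
    empirical correlation; ``n_cc`` beyond the attainable rank is truncated
    with a warning.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("blocks have different sample counts")
    n = a.shape[0]
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    # thin SVDs let the cross-covariance SVD happen on an r_a x r_b core
    ua, sa, _ = _whitened_scores(a, n - 1)
    ub, sb, _ = _whitened_scores(b, n - 1)
    core = (sa[:, None] * (ua.T @ ub)) * sb[None, :]
    p, d, qt = np.linalg.svd(core, full_matrices=False)
    attainable = int((d > d[0] * 1e-12).sum()) if d.size else 0
    if n_cc > attainable:
        warnings.warn(f"n_cc={n_cc} exceeds attainable rank {attainable}; truncating", stacklevel=2)
    k = min(n_cc, attainable)
    u = (ua * sa) @ p[:, :k]
    v = (ub * sb) @ qt.T[:, :k]
    cors = np.array([
        abs(np.corrcoef(u[:, j], v[:, j])[0, 1]) if u[:, j].std() > 0 and v[:, j].std() > 0 else 0.0
        for j in range(k)
    ])
    order = np.argsort(-cors, kind="stable")
    return u[:, order], v[:, order], cors[order]


def _standardize_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = x[:, keep]
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def multicca_merge(omics: list[OmicsMatrix], n_cc: int = 30) -> MergedRepresentation:
    """Fold a list of omics into one samples x components matrix via CCA.

    One omic degenerates to its top ``n_cc`` PCA scores; two omics give the
    column-concatenated canonical variates; three or more left-fold the
    pairwise step over the user-supplied order (the fold is not commutative;
    the order is part of the analysis definition). Columns are standardized.
    """
    if not omics:
        raise ValueError("no omics supplied")
    samples = omics[0].sample_ids
    for om in omics[1:]:
        if om.sample_ids != samples:
            raise ValueError("omics have mismatched sample ids/order")
    scaled = [scale_features(om).values.T for om in omics]  # samples x features
    if len(scaled) == 1:
        x = scaled[0] - scaled[0].mean(axis=0)
        u, s, _ = _whitened_scores(x, min(x.shape[0] - 1, n_cc))
        merged = u * s  # PCA scores
        prov = [(omics[0].omic_label, merged.shape[1], "pca")]
    else:
        merged, v, _ = pairwise_cca(scaled[0], scaled[1], n_cc)
        merged = np.hstack([merged, v])
        prov = [(omics[0].omic_label, merged.shape[1] // 2, "cca"),
                (omics[1].omic_label, merged.shape[1] // 2, "cca")]
        for om, block in zip(omics[2:], scaled[2:]):
            u, v, _ = pairwise_cca(merged, block, n_cc)
            merged = np.hstack([u, v])
            prov.append((om.omic_label, v.shape[1], "cca"))
    return MergedRepresentation(_standardize_cols(merged), list(samples), prov)


def wgcna_merge(omics: list[OmicsMatrix], **wgcna_params) -> MergedRepresentation:
    """Concatenate per-omic module eigengenes into one samples x modules matrix.

    Each omic is decomposed with :func:`cwgcna.network.build_modules`; an omic
    yielding no modules contributes nothing (with a warning).
    """
    if not omics:
        raise ValueError("no omics supplied")
    samples = omics[0].sample_ids
    blocks, prov = [], []
    for om in omics:
        if om.sample_ids != samples:
            raise ValueError("omics have mismatched sample ids/order")
        ms = build_modules(om, **wgcna_params)
        if not ms.module_labels:
            warnings.warn(f"omic {om.omic_label!r} yielded no modules; skipped", stacklevel=2)
            continue
        blocks.append(ms.eigengenes.to_numpy(float).T)  # samples x modules
        prov.append((om.omic_label, len(ms.module_labels), "wgcna-eigengene"))
    if not blocks:
        raise ValueError("no omic yielded modules")
    return MergedRepresentation(_standardize_cols(np.hstack(blocks)), list(samples), prov)


def cluster_select_k(
    rep: MergedRepresentation,
    k_candidates: list[int],
    seed: int = 0,
    n_init: int = 25,
) -> ClusterResult:
    """k-means over candidate k; optimal k by 2-of-3 internal-index vote.

    Per candidate, k-means (``n_init`` restarts, seeded) is fitted on the
    merged matrix and the Silhouette, Calinski-Harabasz and Davies-Bouldin
    indices are computed. The chosen k is the majority vote of (argmax
    silhouette, argmax calinski, argmin davies); when all three disagree the
    silhouette winner is used. A k producing an empty or singleton cluster is
    retried up to 5 times with new initialisations, then marked invalid.
    """
    x = rep.matrix
    n = x.shape[0]
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if any(k < 2 or k > n - 1 for k in k_candidates):
        raise ValueError("k candidates must lie in 2..n_samples-1")
    rows, per_k_labels = [], {}
    rng = np.random.default_rng(seed)
    for k in k_candidates:
        labels, valid = None, False
        for _ in range(5):
            km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(2**31 - 1)))
            cand = km.fit_predict(x)
            if np.unique(cand).size == k and np.bincount(cand).min() >= 2:
                labels, valid = cand, True
                break
        if not valid:
            rows.append({"k": k, "silhouette": np.nan, "calinski": np.nan,
                         "davies": np.nan, "valid": False})
            continue
        per_k_labels[k] = labels
        rows.append({
            "k": k,
            "silhouette": silhouette_score(x, labels),
            "calinski": calinski_harabasz_score(x, labels),
            "davies": davies_bouldin_score(x, labels),
            "valid": True,
        })
    indices = pd.DataFrame(rows).set_index("k")
    valid = indices[indices["valid"]]
    if valid.empty:
        raise ValueError("no candidate k produced a valid clustering")
    votes = [
        int(valid["silhouette"].idxmax()),
        int(valid["calinski"].idxmax()),
        int(valid["davies"].idxmin()),
    ]
    counts = pd.Series(votes).value_counts()
    chosen = int(counts.index[0]) if counts.iloc[0] >= 2 else votes[0]
    return ClusterResult(per_k_labels[chosen], chosen, indices, per_k_labels)
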