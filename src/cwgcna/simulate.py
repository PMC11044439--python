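"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed and returns the ground
truth it planted, so module recovery, driver/passenger mediation calls,
multi-omic clustering and imbalance handling can all be tested offline.

Block-correlated features use the factor construction
``x = sqrt(rho) * f + sqrt(1 - rho) * eps`` with a shared standard-normal
factor ``f`` per block, which gives an exact target within-block correlation
of ``rho``.

The mediation scenario plants a structurally identifiable causal graph:

* driver features sit upstream of the phenotype — each loads (slope ``a``)
  on its own latent and pushes the binary group through a logistic link
  (slope ``b``);
* the group shifts the module factor (separation ``module_shift`` in factor
  sd units), and passenger features load on that shifted factor, inheriting
  a ``passenger_shift``-sd group difference;
* null module features are noise plus a confounder effect; the confounder
  also enters the group's logistic link.

Under this graph "module -> feature -> group" mediation is significant for
drivers only and "group -> feature -> module" for passengers only, as exact
conditional independencies rather than power accidents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import OmicsMatrix, PhenotypeTable

__all__ = [
    "simulate_modular_expression",
    "MediationScenario",
    "simulate_mediation_phenotype",
    "simulate_multiomics_clusters",
    "simulate_imbalanced_classes",
]


def simulate_modular_expression(
    n_samples: int = 100,
    blocks: list[tuple[int, float]] = ((60, 0.8), (40, 0.8)),
    n_background: int = 0,
    seed: int = 0,
    omic_label: str = "RNA",
) -> tuple[OmicsMatrix, dict[str, str]]:
    """Block-correlated expression: per block a latent factor f ~ N(0,1) and
    features sqrt(rho)*f + sqrt(1-rho)*noise; background features are i.i.d.
    noise. Returns the matrix and the true feature -> block assignment
    ("block1", ..., "background")."""
    rng = np.random.default_rng(seed)
    rows, ids, truth = [], [], {}
    for b, (size, rho) in enumerate(blocks, start=1):
        if not 0 <= rho < 1:
            raise ValueError("rho must be in [0, 1)")
        f = rng.standard_normal(n_samples)
        for j in range(size):
            fid = f"b{b}_g{j}"
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n_samples))
            ids.append(fid)
            truth[fid] = f"block{b}"
    for j in range(n_background):
        fid = f"bg_g{j}"
        rows.append(rng.standard_normal(n_samples))
        ids.append(fid)
        truth[fid] = "background"
    m = OmicsMatrix(np.vstack(rows), ids, [f"s{i}" for i in range(n_samples)], omic_label)
    return m, truth


@dataclass
class MediationScenario:
    """Generated mediation fixture: data, phenotypes and planted truth."""

    matrix: OmicsMatrix
    phenotypes: PhenotypeTable
    truth: pd.DataFrame  # feature, role in {driver, passenger, null, background}
    assignment: dict[str, str]  # feature -> module label (planted)
    group: np.ndarray = field(repr=False, default=None)


def simulate_mediation_phenotype(
    n_samples: int = 300,
    n_drivers: int = 1,
    n_passengers: int = 20,
    n_nulls: int = 30,
    a: float = 0.8,
    b: float = 1.5,
    passenger_shift: float = 0.6,
    module_shift: float = 2.0,
    confounder_on_group: float = 0.8,
    confounder_on_features: float = 0.3,
    n_background: int = 0,
    seed: int = 0,
) -> MediationScenario:
    """Plant forward (driver) and reverse (passenger) mediation chains.

    The passenger loading on the module factor is chosen so that passenger
    features have unit variance and a group difference of
    ``passenger_shift`` standard deviations; with the defaults
    (module_shift=2) the loading is 0.3.
    """
    if n_drivers < 1 or n_passengers < 0 or n_nulls < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    n = n_samples
    conf = rng.standard_normal(n)

    # drivers: own upstream latent, slope a; unit marginal variance
    drivers = np.vstack([
        a * rng.standard_normal(n) + np.sqrt(max(1 - a**2, 1e-9)) * rng.standard_normal(n)
        for _ in range(n_drivers)
    ])
    logit = b * drivers.mean(axis=0) + confounder_on_group * conf
    group = (rng.uniform(size=n) < expit(logit)).astype(float)

    # module factor shifted by the group; passengers load on it
    factor = module_shift * group + rng.standard_normal(n)
    loading = passenger_shift / module_shift
    var_factor = module_shift**2 / 4.0 + 1.0
    noise_var = max(1.0 - loading**2 * var_factor, 0.05)
    passengers = np.vstack([
        loading * factor + np.sqrt(noise_var) * rng.standard_normal(n)
        for _ in range(n_passengers)
    ]) if n_passengers else np.empty((0, n))

    nulls = np.vstack([
        confounder_on_features * conf
        + np.sqrt(max(1 - confounder_on_features**2, 1e-9)) * rng.standard_normal(n)
        for _ in range(n_nulls)
    ]) if n_nulls else np.empty((0, n))

    background = rng.standard_normal((n_background, n)) if n_background else np.empty((0, n))

    ids, roles, assignment = [], [], {}
    for j in range(n_drivers):
        ids.append(f"driver_{j}"); roles.append("driver")
    for j in range(n_passengers):
        ids.append(f"passenger_{j}"); roles.append("passenger")
    for j in range(n_nulls):
        ids.append(f"null_{j}"); roles.append("null")
    for fid in ids:
        assignment[fid] = "ME1"
    for j in range(n_background):
        fid = f"bg_{j}"
        ids.append(fid); roles.append("background"); assignment[fid] = "ME0"

    values = np.vstack([drivers, passengers, nulls, background])
    samples = [f"s{i}" for i in range(n)]
    m = OmicsMatrix(values, ids, samples, "RNA")
    ph = PhenotypeTable(
        pd.DataFrame({"group": np.where(group == 1, "g1", "g0"), "conf": conf}, index=samples),
        response="group",
        confounders=["conf"],
    )
    truth = pd.DataFrame({"feature": ids, "role": roles})
    return MediationScenario(m, ph, truth, assignment, group)


def simulate_multiomics_clusters(
    cluster_sizes: tuple[int, ...] = (50, 50, 50),
    omics: list[tuple[str, int, int]] = (("RNA", 120, 30), ("DNAm", 150, 30), ("miRNA", 60, 15)),
    separation: float = 8.0,
    seed: int = 0,
) -> tuple[list[OmicsMatrix], np.ndarray]:
    """Shared sample clusters across several omics.

    Each omic's informative features get cluster-specific means drawn from
    N(0, (separation/sqrt(2))^2) per (cluster, feature) — so two clusters are
    ``separation`` noise-sd apart on an informative feature in expectation —
    plus unit noise; remaining features are pure noise. Cluster sizes are
    honored exactly.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.repeat(c, s) for c, s in enumerate(cluster_sizes)])
    n = labels.size
    samples = [f"s{i}" for i in range(n)]
    out = []
    for label, n_features, n_informative in omics:
        if n_informative > n_features:
            raise ValueError("n_informative exceeds n_features")
        centers = rng.standard_normal((len(cluster_sizes), n_informative)) * separation / np.sqrt(2)
        vals = rng.standard_normal((n_features, n))
        vals[:n_informative] += centers[labels].T
        ids = [f"{label}_f{j}" for j in range(n_features)]
        out.append(OmicsMatrix(vals, ids, samples, label))
    return out, labels


def simulate_imbalanced_classes(
    class_sizes: tuple[int, ...] = (400, 40),
    n_features: int = 150,
    n_informative: int = 10,
    class_shift: float = 0.5,
    seed: int = 0,
) -> tuple[OmicsMatrix, np.ndarray, dict]:
    """Imbalanced classes with overlapping Gaussian structure.

    Informative features are shifted by ``class_shift`` noise-sd between
    consecutive classes, so the shift controls the Bayes error monotonically;
    the remaining features are noise. Returns (matrix, labels, info) where
    ``info`` carries the informative ids and true per-class means.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.repeat(f"c{c}", s) for c, s in enumerate(class_sizes)])
    n = labels.size
    vals = rng.standard_normal((n_features, n))
    means = np.array([[c * class_shift] * n_informative for c in range(len(class_sizes))])
    for c in range(len(class_sizes)):
        vals[:n_informative, labels == f"c{c}"] += means[c][:, None]
    ids = [f"f{j}" for j in range(n_features)]
    m = OmicsMatrix(vals, ids, [f"s{i}" for i in range(n)], "omic")
    info = {"informative": ids[:n_informative], "class_means": means}
    return m, labels, info
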