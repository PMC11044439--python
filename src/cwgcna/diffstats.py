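"""Confounder screening and moderated differential testing.

Two statistical workhorses live here:

* :func:`type3_anova_screen` — per-feature linear models with every phenotype
  variable as a predictor, type-III (marginal) sums of squares per variable
  via full-vs-reduced fits under sum-to-zero coding, averaged over the most
  variable features. The per-variable mean F summarises how much variance
  each phenotype variable explains dataset-wide, flagging confounders worth
  adjusting for.

* :func:`moderated_fit` — per-unit OLS with empirical-Bayes variance
  shrinkage: a scaled inverse-chi-square prior (s0^2, d0) is fitted to the
  residual variances by matching the first two moments of log s^2, each
  unit's variance is shrunk towards s0^2, and the moderated t uses d0 + d
  degrees of freedom. This stabilises variance estimates when many units are
  tested with few samples, as in eigengene / within-module feature testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import OmicsMatrix, PhenotypeTable
from .network import ModuleSet

__all__ = [
    "bh_adjust",
    "AnovaScreenResult",
    "type3_anova_screen",
    "moderated_fit",
    "diff_modules",
    "diff_features_within_module",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# type-III ANOVA screen
# ---------------------------------------------------------------------------


def _effect_code(v: pd.Series) -> np.ndarray:
    """Sum-to-zero (effects) coding: L-1 columns, last level coded -1."""
    levels = sorted(v.unique().tolist(), key=str)
    cols = np.zeros((len(v), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (v == lev).to_numpy(float)
    cols[(v == levels[-1]).to_numpy(bool), :] = -1.0
    return cols


def _variable_blocks(ph: PhenotypeTable, variables: list[str]) -> dict[str, np.ndarray]:
    blocks = {}
    for name in variables:
        v = ph.data[name]
        if v.dtype.kind in "biufc":
            blocks[name] = v.to_numpy(float)[:, None]
        else:
            blocks[name] = _effect_code(v.astype("category").astype(str))
    return blocks


@dataclass
class AnovaScreenResult:
    """Mean MSS / F / p per phenotype variable plus the per-feature table."""

    summary: pd.DataFrame  # index = variable; columns = mean_MSS, mean_F, mean_p
    per_feature: pd.DataFrame  # columns = feature, variable, MSS, F, p


def type3_anova_screen(
    m: OmicsMatrix,
    ph: PhenotypeTable,
    top_n: int = 10000,
    variables: list[str] | None = None,
) -> AnovaScreenResult:
    """Type-III ANOVA of every phenotype variable over the most variable features.

    For each of the ``top_n`` most variable features one linear model with all
    phenotype variables as predictors is fitted (categoricals sum-to-zero
    coded); each variable's marginal contribution is the SSR increase when its
    columns are dropped from the full model. The per-variable MSS, F and p are
    averaged across features.
    """
    ph = ph.align_to(m)
    variables = variables or [ph.response] + list(ph.confounders)
    blocks = _variable_blocks(ph, variables)
    n = m.n_samples
    x_full = np.hstack([np.ones((n, 1))] + [blocks[v] for v in variables])
    p_full = x_full.shape[1]
    if n <= p_full:
        raise ValueError(f"n_samples={n} <= model df={p_full}")
    if np.linalg.matrix_rank(x_full) < p_full:
        for i, vi in enumerate(variables):
            for vj in variables[i + 1:]:
                sub = np.hstack([np.ones((n, 1)), blocks[vi], blocks[vj]])
                if np.linalg.matrix_rank(sub) < sub.shape[1]:
                    raise ValueError(f"aliased (collinear) variables: {vi!r} and {vj!r}")
        raise ValueError("design matrix is rank deficient")

    variances = m.values.var(axis=1, ddof=1)
    order = np.argsort(-variances, kind="stable")[: min(top_n, m.n_features)]
    y = m.values[order].T  # samples x features
    features = [m.feature_ids[i] for i in order]

    def ssr(x: np.ndarray) -> np.ndarray:
        q, _ = np.linalg.qr(x)
        resid = y - q @ (q.T @ y)
        return (resid**2).sum(axis=0)

    ssr_full = ssr(x_full)
    df_res = n - p_full
    ms_res = ssr_full / df_res
    rows = []
    for v in variables:
        others = [b for name, b in blocks.items() if name != v]
        x_red = np.hstack([np.ones((n, 1))] + others) if others else np.ones((n, 1))
        delta = np.maximum(ssr(x_red) - ssr_full, 0.0)
        df_v = blocks[v].shape[1]
        mss = delta / df_v
        f = mss / ms_res
        pvals = stats.f.sf(f, df_v, df_res)
        rows.append(pd.DataFrame({"feature": features, "variable": v, "MSS": mss, "F": f, "p": pvals}))
    per_feature = pd.concat(rows, ignore_index=True)
    summary = (
        per_feature.groupby("variable", sort=False)[["MSS", "F", "p"]]
        .mean()
        .rename(columns={"MSS": "mean_MSS", "F": "mean_F", "p": "mean_p"})
    )
    return AnovaScreenResult(summary, per_feature)


# ---------------------------------------------------------------------------
# moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (s0^2, d0) on log s^2."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1) if z.size > 1 else 0.0
    resid_var = var_z - special.polygamma(1, d / 2.0)
    if resid_var > 0:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s0_2 = np.exp(
            e_z
            - (special.polygamma(0, d / 2.0) - np.log(d / 2.0))
            + (special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_2 = np.exp(e_z - (special.polygamma(0, d / 2.0) - np.log(d / 2.0)))
    return float(s0_2), float(d0)


def moderated_fit(
    y: np.ndarray,
    design: np.ndarray,
    coef_of_interest: int,
    unit_ids: list[str] | None = None,
    prior_df: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-unit OLS with empirical-Bayes moderated t for one coefficient.

    Parameters
    ----------
    y
        Units x samples response matrix.
    design
        Samples x p full-rank model matrix (include the intercept).
    coef_of_interest
        Column of ``design`` whose coefficient is tested.
    prior_df
        Override for the prior degrees of freedom d0 (0 = ordinary per-unit
        t; ``np.inf`` = fully pooled variance). Default: estimated by moment
        matching on log s^2.
    """
    y = np.atleast_2d(np.asarray(y, float))
    x = np.asarray(design, float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValueError("y and design sample dimensions differ")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    d = n - p
    if d <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv  # units x p
    resid = y - beta @ x.T
    s2 = (resid**2).sum(axis=1) / d
    c = np.sqrt(xtx_inv[coef_of_interest, coef_of_interest])

    if prior_df is None:
        if y.shape[0] < 2 or np.allclose(s2, s2[0]):
            s0_2, d0 = (float(s2.mean()), np.inf)
        else:
            s0_2, d0 = _fit_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0_2 = float(s2[s2 > 0].mean()) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    eff = beta[:, coef_of_interest]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / (np.sqrt(s2_tilde) * c)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    padj = bh_adjust(pvals)
    units = unit_ids if unit_ids is not None else [str(i) for i in range(y.shape[0])]
    return pd.DataFrame(
        {
            "unit": units,
            "effect": eff,
            "t": t,
            "p": pvals,
            "p_adj": padj,
            "significant": padj < alpha,
        }
    )


def _group_design(ph: PhenotypeTable) -> tuple[np.ndarray, list[str]]:
    """[intercept, group(0/1), confounder columns] design from a phenotype table."""
    group, levels = ph.binary_response_codes()
    conf = ph.confounder_design()
    x = np.hstack([np.ones((len(group), 1)), group[:, None], conf])
    return x, levels


def diff_modules(
    ms: ModuleSet,
    ph: PhenotypeTable,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated group-difference test of every module eigengene.

    The design is [intercept, group, confounders]; the effect column is the
    group coefficient (second level minus reference), BH-adjusted across
    modules.
    """
    if ms.eigengenes.empty:
        return pd.DataFrame(
            columns=["unit", "effect", "t", "p", "p_adj", "significant"]
        )
    samples = list(ms.eigengenes.columns)
    missing = [s for s in samples if s not in ph.data.index]
    if missing:
        raise ValueError(f"phenotype table lacks samples: {missing}")
    ph = PhenotypeTable(ph.data.loc[samples].copy(), ph.response, list(ph.confounders))
    x, _ = _group_design(ph)
    return moderated_fit(
        ms.eigengenes.to_numpy(float), x, 1, unit_ids=list(ms.eigengenes.index),
        prior_df=prior_df, alpha=alpha,
    )


def diff_features_within_module(
    m: OmicsMatrix,
    ms: ModuleSet,
    module_label: str,
    ph: PhenotypeTable,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated group-difference test of one module's features (BH within module)."""
    members = ms.members(module_label)
    if len(members) < 2:
        raise ValueError(f"module {module_label!r} absent or has <2 features")
    sub = m.subset_features(members)
    ph = ph.align_to(sub)
    x, _ = _group_design(ph)
    return moderated_fit(sub.values, x, 1, unit_ids=members, prior_df=prior_df, alpha=alpha)
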