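"""Two-direction causal mediation with inverse-probability weighting.

For each candidate feature of a differential module two mediation models are
fitted with the feature as mediator:

* forward, "module -> feature -> phenotype": exposure = module eigengene,
  outcome = sample group;
* reverse, "phenotype -> feature -> module": exposure = sample group,
  outcome = module eigengene.

The indirect effect is the product a * b of the exposure->mediator slope (a)
and the exposure-adjusted mediator->outcome slope (b). Measured confounders
enter through stabilized inverse-probability weights on the exposure rather
than as regression covariates, so both path models share one adjustment
mechanism; a doubly-robust flag additionally puts them in the path models.
Significance comes from a nonparametric bootstrap (weights re-estimated in
every resample) with percentile CIs and the add-one empirical p-value.

A feature significant only forward is called a *driver* (it plausibly
transmits the module's effect onto the phenotype); significant only reverse,
a *passenger* (it reacts to the phenotype and carries the change into the
module); both, *ambiguous*; neither, *none*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import OmicsMatrix, PhenotypeTable
from .diffstats import bh_adjust
from .network import ModuleSet

__all__ = [
    "MediationSpec",
    "MediationResult",
    "estimate_ipw_weights",
    "test_mediation",
    "causal_screen",
]


# ---------------------------------------------------------------------------
# small weighted fitters (hot path: called inside every bootstrap resample)
# ---------------------------------------------------------------------------


def _wls_coef(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    xw = x * w[:, None]
    return np.linalg.solve(x.T @ xw, xw.T @ y)


class _SeparationError(RuntimeError):
    pass


def _logistic_coef(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, max_iter: int = 30, tol: float = 1e-8
) -> tuple[np.ndarray, bool]:
    """Weighted logistic regression by Newton-Raphson. Returns (coef, converged)."""
    beta = np.zeros(x.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = expit(eta)
        wk = w * mu * (1.0 - mu) + 1e-10
        grad = x.T @ (w * (y - mu))
        hess = x.T @ (x * wk[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 25.0:
        raise _SeparationError("perfect or quasi separation in logistic model")
    return beta, converged


def _is_binary(v: np.ndarray) -> bool:
    return np.unique(v).size == 2


def _as_01(v: np.ndarray) -> np.ndarray:
    levels = np.unique(v)
    return (v == levels[1]).astype(float)


def _raw_weights(exposure: np.ndarray, conf: np.ndarray) -> np.ndarray:
    """Stabilized IPW weights, un-truncated."""
    n = exposure.shape[0]
    if conf.size == 0:
        return np.ones(n)
    x = np.hstack([np.ones((n, 1)), conf])
    if _is_binary(exposure):
        e = _as_01(exposure)
        beta, _ = _logistic_coef(x, e, np.ones(n))
        p_cond = expit(np.clip(x @ beta, -30, 30))
        p_marg = e.mean()
        num = np.where(e == 1, p_marg, 1.0 - p_marg)
        den = np.where(e == 1, p_cond, 1.0 - p_cond)
        return num / np.maximum(den, 1e-12)
    # continuous exposure: Gaussian generalized propensity
    beta = _wls_coef(x, exposure, np.ones(n))
    fitted = x @ beta
    resid = exposure - fitted
    sd_cond = max(float(resid.std(ddof=x.shape[1])), 1e-12)
    mu_marg = float(exposure.mean())
    sd_marg = max(float(exposure.std(ddof=1)), 1e-12)
    log_num = -0.5 * ((exposure - mu_marg) / sd_marg) ** 2 - np.log(sd_marg)
    log_den = -0.5 * (resid / sd_cond) ** 2 - np.log(sd_cond)
    return np.exp(log_num - log_den)


def estimate_ipw_weights(
    exposure: np.ndarray,
    confounders: np.ndarray | None = None,
    truncation: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Stabilized inverse-probability weights for a binary or continuous exposure.

    Binary exposures use a logistic propensity model; continuous exposures a
    Gaussian generalized propensity (linear mean, homoscedastic). With no
    confounders all weights are exactly 1. Weights are truncated at the given
    percentiles to limit the influence of extreme propensities.
    """
    exposure = np.asarray(exposure, float)
    conf = np.empty((exposure.shape[0], 0)) if confounders is None else np.atleast_2d(
        np.asarray(confounders, float)
    )
    if conf.ndim == 2 and conf.shape[0] != exposure.shape[0] and conf.size:
        conf = conf.T
    try:
        w = _raw_weights(exposure, conf)
    except _SeparationError:
        raise ValueError(
            "perfect separation in the propensity model; remove or coarsen the offending confounder"
        )
    if conf.size:
        lo, hi = np.percentile(w, truncation)
        w = np.clip(w, lo, hi)
    return w


# ---------------------------------------------------------------------------
# the product-method mediation test
# ---------------------------------------------------------------------------


@dataclass
class MediationSpec:
    """One mediation problem: exposure -> mediator -> outcome with confounders."""

    exposure: np.ndarray
    mediator: np.ndarray
    outcome: np.ndarray
    confounders: np.ndarray | None = None
    n_boot: int = 500
    weight_truncation: tuple[float, float] = (1.0, 99.0)
    use_ipw: bool = True
    doubly_robust: bool = False

    def __post_init__(self) -> None:
        self.exposure = np.asarray(self.exposure, float)
        self.mediator = np.asarray(self.mediator, float)
        self.outcome = np.asarray(self.outcome, float)
        n = self.exposure.shape[0]
        if self.mediator.shape[0] != n or self.outcome.shape[0] != n:
            raise ValueError("exposure, mediator and outcome lengths differ")
        if self.confounders is not None:
            self.confounders = np.atleast_2d(np.asarray(self.confounders, float))
            if self.confounders.shape[0] != n:
                self.confounders = self.confounders.T
            if self.confounders.shape[0] != n:
                raise ValueError("confounder rows do not match sample count")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


@dataclass
class MediationResult:
    direction: str
    a: float
    b: float
    indirect: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    unstable: bool = False
    p_adj: float = np.nan
    boot_indirect: np.ndarray | None = field(default=None, repr=False)


def _paths(
    exposure: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    conf: np.ndarray | None,
    w: np.ndarray,
    outcome_binary: bool,
    doubly_robust: bool,
) -> tuple[float, float, bool]:
    """a and b path coefficients under weights w. Returns (a, b, converged)."""
    n = exposure.shape[0]
    ones = np.ones((n, 1))
    extra = conf if (doubly_robust and conf is not None and conf.size) else None
    xa = np.hstack([ones, exposure[:, None]] + ([extra] if extra is not None else []))
    a = float(_wls_coef(xa, mediator, w)[1])
    xb = np.hstack([ones, mediator[:, None], exposure[:, None]]
                   + ([extra] if extra is not None else []))
    if outcome_binary:
        coef, conv = _logistic_coef(xb, _as_01(outcome), w)
        b = float(coef[1])
    else:
        b = float(_wls_coef(xb, outcome, w)[1])
        conv = True
    return a, b, conv


def test_mediation(spec: MediationSpec, seed: int = 0) -> MediationResult:
    """Product-method mediation test with IPW and a nonparametric bootstrap.

    The a path regresses mediator on exposure, the b path regresses outcome
    on mediator + exposure (weighted logistic when the outcome is binary);
    indirect = a * b. Samples are resampled with replacement ``n_boot``
    times, weights re-estimated inside each resample; the two-sided p uses
    the add-one sign-crossing rule and the CI is the 2.5/97.5 percentile
    band. A result is flagged unstable when >20% of resamples fail to
    converge.
    """
    if np.std(spec.mediator) == 0:
        raise ValueError("mediator is constant")
    outcome_binary = _is_binary(spec.outcome)
    conf = spec.confounders if spec.use_ipw else None
    w = estimate_ipw_weights(spec.exposure, conf, spec.weight_truncation)
    a, b, _ = _paths(
        spec.exposure, spec.mediator, spec.outcome, spec.confounders, w,
        outcome_binary, spec.doubly_robust,
    )
    rng = np.random.default_rng(seed)
    n = spec.exposure.shape[0]
    boot = np.empty(spec.n_boot)
    failures = 0
    for i in range(spec.n_boot):
        idx = rng.integers(0, n, n)
        try:
            wb = estimate_ipw_weights(spec.exposure[idx], None if conf is None else conf[idx],
                                      spec.weight_truncation)
            ab, bb, conv = _paths(
                spec.exposure[idx], spec.mediator[idx], spec.outcome[idx],
                None if spec.confounders is None else spec.confounders[idx],
                wb, outcome_binary, spec.doubly_robust,
            )
            if not conv:
                failures += 1
            boot[i] = ab * bb
        except (ValueError, _SeparationError, np.linalg.LinAlgError):
            failures += 1
            boot[i] = np.nan
    ok = boot[np.isfinite(boot)]
    nb = ok.size
    if nb == 0:
        raise ValueError("all bootstrap resamples failed")
    n_le = int((ok <= 0).sum())
    n_ge = int((ok >= 0).sum())
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (nb + 1))
    ci_low, ci_high = np.percentile(ok, [2.5, 97.5])
    return MediationResult(
        direction="forward",
        a=a, b=b, indirect=a * b,
        ci_low=float(ci_low), ci_high=float(ci_high),
        p=float(p), n_boot=nb,
        unstable=failures > 0.2 * spec.n_boot,
        boot_indirect=ok,
    )


# ---------------------------------------------------------------------------
# module-level screen
# ---------------------------------------------------------------------------

LABELS = ("driver", "passenger", "ambiguous", "none")


def _loo_eigengene(x_std: np.ndarray, drop: int) -> np.ndarray:
    """Module eigengene recomputed without one feature (rows standardized)."""
    sub = np.delete(x_std, drop, axis=0)
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    pc1 = vt[0]
    if pc1 @ sub.mean(axis=0) < 0:
        pc1 = -pc1
    return pc1 / pc1.std(ddof=1)


def causal_screen(
    m: OmicsMatrix,
    ms: ModuleSet,
    module_label: str,
    diff: pd.DataFrame,
    ph: PhenotypeTable,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    doubly_robust: bool = True,
    loo_eigengene: bool = True,
) -> pd.DataFrame:
    """Run forward and reverse mediation for a module's differential features.

    ``diff`` is the within-module differential table; only rows flagged
    significant are tested. BH adjustment is applied within each direction
    across the tested features. Returns a long table with one row per
    (feature, direction) carrying a, b, indirect, CI, p, p_adj and the
    feature's driver/passenger label.

    Two safeguards are on by default because the eigengene is built from the
    very features under test:

    * ``loo_eigengene`` — the eigengene used as the reverse-direction
      *outcome* is recomputed without the tested feature; otherwise the
      feature's own loading guarantees a mediator-outcome association and
      biases upstream features towards "ambiguous". The forward-direction
      *exposure* keeps the full module summary: there the mediator's
      contribution belongs to the exposure, and removing it turns the
      eigengene into an errors-in-variables proxy whose attenuation leaks
      the mediator's factor content into the b-path, faking forward signal
      for downstream features.
    * ``doubly_robust`` — confounders also enter the path models as
      covariates. Exposure IPW alone cannot remove mediator-outcome
      confounding (a confounder that loads on module members sits inside the
      eigengene, and conditioning on the group opens a collider path to the
      mediator), which again manufactures reverse-direction signal.

    Note on resolution: the smallest attainable bootstrap p is
    2/(n_boot+1), so n_boot must exceed roughly 40x the number of tested
    features for a single true positive to survive BH at 0.05.
    """
    if module_label not in ms.module_labels:
        raise ValueError(f"module {module_label!r} not present")
    tested = [u for u in diff.loc[diff["significant"], "unit"] if ms.assignment.get(u) == module_label]
    eigengene = ms.eigengenes.loc[module_label].to_numpy(float)
    sample_order = list(ms.eigengenes.columns)
    sub = m.subset_samples(sample_order)
    ph = ph.align_to(sub)
    group, _ = ph.binary_response_codes()
    conf = ph.confounder_design()
    conf = conf if conf.size else None
    feature_pos = {f: i for i, f in enumerate(sub.feature_ids)}
    members = ms.members(module_label)
    member_vals = sub.values[[feature_pos[f] for f in members]]
    mu = member_vals.mean(axis=1, keepdims=True)
    sd = member_vals.std(axis=1, ddof=1, keepdims=True)
    x_std = (member_vals - mu) / np.where(sd > 0, sd, 1.0)
    member_row = {f: i for i, f in enumerate(members)}

    rows = []
    rng = np.random.default_rng(seed)
    for feat in tested:
        values = sub.values[feature_pos[feat]]
        eig_out = _loo_eigengene(x_std, member_row[feat]) if loo_eigengene else eigengene
        seeds = rng.integers(0, 2**31 - 1, 2)
        for direction, (e, y) in {
            "forward": (eigengene, group),
            "reverse": (group, eig_out),
        }.items():
            try:
                res = test_mediation(
                    MediationSpec(e, values, y, conf, n_boot=n_boot,
                                  doubly_robust=doubly_robust),
                    seed=int(seeds[0] if direction == "forward" else seeds[1]),
                )
                rows.append({
                    "module": module_label, "feature": feat, "direction": direction,
                    "a": res.a, "b": res.b, "indirect": res.indirect,
                    "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                    "unstable": res.unstable,
                })
            except (ValueError, np.linalg.LinAlgError):
                rows.append({
                    "module": module_label, "feature": feat, "direction": direction,
                    "a": np.nan, "b": np.nan, "indirect": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "unstable": True,
                })
    out = pd.DataFrame(rows, columns=["module", "feature", "direction", "a", "b",
                                      "indirect", "ci_low", "ci_high", "p", "unstable"])
    out["p_adj"] = np.nan
    for direction in ("forward", "reverse"):
        sel = (out["direction"] == direction) & out["p"].notna()
        if sel.any():
            out.loc[sel, "p_adj"] = bh_adjust(out.loc[sel, "p"].to_numpy())

    sig = {}
    for feat in tested:
        f_rows = out[out["feature"] == feat]
        fwd = bool((f_rows.loc[f_rows["direction"] == "forward", "p_adj"] < alpha).any())
        rev = bool((f_rows.loc[f_rows["direction"] == "reverse", "p_adj"] < alpha).any())
        sig[feat] = ("ambiguous" if (fwd and rev) else "driver" if fwd
                     else "passenger" if rev else "none")
    out["label"] = out["feature"].map(sig)
    return out
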