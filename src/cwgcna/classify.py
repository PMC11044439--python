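"""Imbalance-aware multi-omics ensemble classification.

Per omic the workflow is: standardize features, screen them by one-way ANOVA
against the class labels (p < 0.05, unadjusted), build base-learner training
sets according to the balancing mode, select features by elastic net on each
base set, keep the recurrently selected ones, and train one base learner
(linear SVM or multinomial logistic regression) per base set. Omic-level
class probabilities are the mean over base learners; multi-omic predictions
average the omic-level probability vectors and take the argmax.

Balancing modes:

1. bagging-SMOTE — 10 base sets; each class is bootstrapped and minority
   classes are topped up with SMOTE-interpolated synthetic samples to the
   majority size, so every base set is exactly class-balanced;
2. plain bagging — 10 bootstrap resamples of the original data;
3. none — the original data once (single base learner).

SMOTE synthesises a minority point by interpolating uniformly on the segment
between a random minority sample and one of its k nearest minority
neighbours; it is applied only inside base training sets, never to
evaluation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .datamodel import OmicsMatrix

__all__ = [
    "EnsembleModel",
    "anova_screen_features",
    "smote_oversample",
    "build_base_datasets",
    "train_ensemble",
    "predict_ensemble",
]


def anova_screen_features(m: OmicsMatrix, labels: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Features whose one-way ANOVA against the class labels has p < alpha.

    The p-values are unadjusted by design: the screen is a permissive
    pre-filter ahead of elastic-net selection. Zero-variance features are
    dropped.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >=2 classes")
    x = m.values  # features x samples
    n = x.shape[1]
    overall_mean = x.mean(axis=1, keepdims=True)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for c in classes:
        sel = labels == c
        xc = x[:, sel]
        mc = xc.mean(axis=1, keepdims=True)
        ss_between += sel.sum() * (mc[:, 0] - overall_mean[:, 0]) ** 2
        ss_within += ((xc - mc) ** 2).sum(axis=1)
    df1, df2 = classes.size - 1, n - classes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
        p = stats.f.sf(f, df1, df2)
    # perfect separators (zero within-class variance) are kept, constants dropped
    p = np.where((ss_within == 0) & (ss_between > 0), 0.0, p)
    keep = (ss_between + ss_within > 0) & (p < alpha)
    return [fid for fid, k in zip(m.feature_ids, keep) if k]


def smote_oversample(
    x_minority: np.ndarray, n_new: int, rng: np.random.Generator, k: int = 5
) -> np.ndarray:
    """SMOTE: ``n_new`` synthetic points interpolated uniformly on segments
    between minority samples and their k nearest minority neighbours."""
    m = x_minority.shape[0]
    if m < 2:
        raise ValueError("SMOTE needs >=2 minority samples")
    k_eff = min(k, m - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x_minority)
    _, nbr = nn.kneighbors(x_minority)
    nbr = nbr[:, 1:]  # drop self
    base = rng.integers(0, m, n_new)
    pick = nbr[base, rng.integers(0, k_eff, n_new)]
    gamma = rng.uniform(0.0, 1.0, n_new)[:, None]
    return x_minority[base] + gamma * (x_minority[pick] - x_minority[base])


def build_base_datasets(
    x: np.ndarray,
    labels: np.ndarray,
    mode: int,
    seed: int = 0,
    n_base: int = 10,
    smote_k: int = 5,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Base-learner training sets (samples x features) for the given mode.

    Mode 1 returns ``n_base`` exactly class-balanced sets (bootstrap + SMOTE
    top-up to the majority size); mode 2 returns ``n_base`` plain bootstraps;
    mode 3 returns the original data once.
    """
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    if mode not in (1, 2, 3):
        raise ValueError("mode must be 1, 2 or 3")
    if mode == 3:
        return [(x.copy(), labels.copy())]
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    out = []
    if mode == 2:
        for _ in range(n_base):
            idx = rng.integers(0, n, n)
            out.append((x[idx], labels[idx]))
        return out
    # mode 1: bagging-SMOTE
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("mode 1 needs >=2 samples per class (SMOTE undefined otherwise)")
    n_major = int(counts.max())
    for _ in range(n_base):
        xs, ys = [], []
        for c, n_c in zip(classes, counts):
            pool = x[labels == c]
            boot = pool[rng.integers(0, n_c, n_c)]
            if n_c < n_major:
                boot = np.vstack([boot, smote_oversample(boot, n_major - n_c, rng, smote_k)])
            xs.append(boot)
            ys.append(np.repeat(c, n_major))
        out.append((np.vstack(xs), np.concatenate(ys)))
    return out


@dataclass
class _OmicModel:
    omic_label: str
    feature_ids: list[str]  # recurrent features, in training order
    center: np.ndarray
    scale: np.ndarray
    screened: list[str]
    per_learner_selected: list[list[str]]
    learners: list


@dataclass
class EnsembleModel:
    """Fitted multi-omic ensemble: per-omic base learners + soft-vote rule."""

    mode: int
    learner: str
    classes: np.ndarray
    omics: list[_OmicModel] = field(default_factory=list)

    @property
    def n_base_learners(self) -> int:
        return len(self.omics[0].learners) if self.omics else 0


def _make_learner(kind: str, seed: int):
    if kind == "svm":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if kind == "mlr":
        return LogisticRegression(max_iter=2000)
    raise ValueError(f"unknown learner {kind!r}")


def _elastic_net_select(
    x: np.ndarray, y: np.ndarray, feature_ids: list[str], seed: int
) -> list[str]:
    """Features with a nonzero elastic-net coefficient (any class); the
    penalty strength is chosen by internal 3-fold CV, mixing fixed at 0.5."""
    enet = LogisticRegressionCV(
        Cs=[0.05, 0.5, 5.0], cv=3, penalty="elasticnet", solver="saga",
        l1_ratios=[0.5], max_iter=3000, tol=1e-3, random_state=seed, n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(x, y)
    nonzero = np.any(np.abs(enet.coef_) > 1e-8, axis=0)
    return [fid for fid, nz in zip(feature_ids, nonzero) if nz]


def train_ensemble(
    omics: list[OmicsMatrix],
    labels: np.ndarray,
    mode: int = 1,
    learner: str = "svm",
    seed: int = 0,
    n_base: int = 10,
    recurrence: float = 0.5,
    screen_alpha: float = 0.05,
) -> EnsembleModel:
    """Fit the per-omic bagging(-SMOTE) elastic-net + SVM/MLR ensemble.

    ``recurrence`` is the fraction of base learners in which a feature must be
    elastic-net-selected to enter the final model (mode 3 uses its single
    fit's selection). An empty recurrent set falls back to the 50 smallest
    screen p-values with a warning.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    samples = omics[0].sample_ids
    for om in omics[1:]:
        if om.sample_ids != samples:
            raise ValueError("omics have mismatched sample ids/order")
    if len(labels) != len(samples):
        raise ValueError("labels do not match sample count")
    model = EnsembleModel(mode=mode, learner=learner, classes=classes)
    rng = np.random.default_rng(seed)
    for om in omics:
        omic_seed = int(rng.integers(2**31 - 1))
        sd = om.values.std(axis=1, ddof=1)
        keep = sd > 0
        sub = OmicsMatrix(om.values[keep], [f for f, k in zip(om.feature_ids, keep) if k],
                          list(om.sample_ids), om.omic_label)
        screened = anova_screen_features(sub, labels, alpha=screen_alpha)
        if not screened:
            # permissive fallback: keep the 50 most class-associated features
            f_res = _screen_pvalues(sub, labels)
            screened = f_res.nsmallest(min(50, len(f_res))).index.tolist()
            warnings.warn(f"omic {om.omic_label!r}: ANOVA screen empty; "
                          f"falling back to top {len(screened)} features", stacklevel=2)
        sub = sub.subset_features(screened)
        center = sub.values.mean(axis=1)
        scale = sub.values.std(axis=1, ddof=1)
        x = ((sub.values - center[:, None]) / scale[:, None]).T  # samples x features
        base_sets = build_base_datasets(x, labels, mode, seed=omic_seed, n_base=n_base)
        per_sel = [
            _elastic_net_select(bx, by, screened, omic_seed + j)
            for j, (bx, by) in enumerate(base_sets)
        ]
        if mode == 3:
            recurrent = list(per_sel[0])
        else:
            tally = pd.Series([f for sel in per_sel for f in sel]).value_counts()
            recurrent = sorted(tally[tally >= recurrence * len(base_sets)].index.tolist(),
                               key=screened.index)
        if not recurrent:
            f_res = _screen_pvalues(sub, labels)
            recurrent = f_res.nsmallest(min(50, len(f_res))).index.tolist()
            warnings.warn(f"omic {om.omic_label!r}: empty recurrent set; "
                          f"falling back to top {len(recurrent)} screen features", stacklevel=2)
        cols = [screened.index(f) for f in recurrent]
        learners = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            for j, (bx, by) in enumerate(base_sets):
                clf = _make_learner(learner, omic_seed + 1000 + j)
                clf.fit(bx[:, cols], by)
                learners.append(clf)
        model.omics.append(_OmicModel(
            omic_label=om.omic_label,
            feature_ids=recurrent,
            center=center[cols], scale=scale[cols],
            screened=screened, per_learner_selected=per_sel, learners=learners,
        ))
    return model


def _screen_pvalues(m: OmicsMatrix, labels: np.ndarray) -> pd.Series:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    groups = [m.values[:, labels == c] for c in classes]
    f, p = stats.f_oneway(*groups, axis=1)
    return pd.Series(p, index=m.feature_ids)


def predict_ensemble(
    model: EnsembleModel, omics: list[OmicsMatrix]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predict classes for new samples; deterministic given the model.

    Features are aligned by name (row order is irrelevant); every recurrent
    feature of every trained omic must be present. Returns (labels,
    samples x classes probability table); probabilities sum to 1 per sample.
    """
    by_label = {om.omic_label: om for om in omics}
    samples = omics[0].sample_ids
    for om in omics[1:]:
        if om.sample_ids != samples:
            raise ValueError("omics have mismatched sample ids/order")
    probs = []
    for omodel in model.omics:
        if omodel.omic_label not in by_label:
            raise ValueError(f"omic {omodel.omic_label!r} was trained but is absent at prediction")
        om = by_label[omodel.omic_label]
        missing = [f for f in omodel.feature_ids if f not in om.feature_ids]
        if missing:
            raise ValueError(f"omic {omodel.omic_label!r} lacks trained features: {missing}")
        sub = om.subset_features(omodel.feature_ids)
        x = ((sub.values - omodel.center[:, None]) / omodel.scale[:, None]).T
        omic_prob = np.zeros((x.shape[0], model.classes.size))
        for clf in omodel.learners:
            p = clf.predict_proba(x)
            order = [list(clf.classes_).index(c) for c in model.classes]
            omic_prob += p[:, order]
        probs.append(omic_prob / len(omodel.learners))
    mean_prob = np.mean(probs, axis=0)
    mean_prob = mean_prob / mean_prob.sum(axis=1, keepdims=True)
    labels = model.classes[np.argmax(mean_prob, axis=1)]
    return labels, pd.DataFrame(mean_prob, index=samples, columns=[str(c) for c in model.classes])
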