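"""Type-III ANOVA screen, moderated t, and differential module/feature tests."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cwgcna.datamodel import OmicsMatrix, PhenotypeTable
from cwgcna.diffstats import (
    bh_adjust,
    diff_features_within_module,
    diff_modules,
    moderated_fit,
    type3_anova_screen,
)
from cwgcna.network import compute_eigengenes
from cwgcna.simulate import simulate_mediation_phenotype


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
def test_bh_is_monotone_and_dominates_raw(pvals):
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def _pheno(n, group, extra=None):
    data = {"group": group}
    if extra:
        data.update(extra)
    df = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
    return PhenotypeTable(df, "group", [k for k in (extra or {})])


def _matrix(values, prefix="g"):
    values = np.atleast_2d(values)
    return OmicsMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{i}" for i in range(values.shape[1])],
        "RNA",
    )


class TestType3Anova:
    def test_constructed_signal_dominates(self):
        rng = np.random.default_rng(0)
        n = 40
        group = np.repeat(["a", "b"], n // 2)
        other = rng.normal(size=n)
        signal = (group == "b").astype(float) + 1e-6 * rng.normal(size=n)
        m = _matrix(np.vstack([signal, rng.normal(size=(5, n))]))
        ph = _pheno(n, group, {"other": other})
        res = type3_anova_screen(m, ph, top_n=6)
        per = res.per_feature
        f_group = per[(per.feature == "g0") & (per.variable == "group")]["F"].iloc[0]
        assert f_group > 1e6
        assert res.summary.loc["other", "mean_F"] < 5

    def test_null_mean_f_near_one(self):
        rng = np.random.default_rng(5)
        n = 60
        m = _matrix(rng.normal(size=(100, n)))
        ph = _pheno(n, np.tile(["a", "b"], n // 2),
                    {"v2": np.repeat(["x", "y"], n // 2)})
        res = type3_anova_screen(m, ph, top_n=100)
        assert 0.7 <= res.summary.loc["group", "mean_F"] <= 1.4
        assert 0.7 <= res.summary.loc["v2", "mean_F"] <= 1.4

    def test_single_continuous_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        n = 25
        phen = rng.normal(size=n)
        y = 2.0 * phen + rng.normal(size=n)
        m = _matrix(y)
        ph = _pheno(n, phen)
        res = type3_anova_screen(m, ph, top_n=1)
        # independent OLS oracle
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(phen)).fit()
        assert res.per_feature["F"].iloc[0] == pytest.approx(fit.tvalues[1] ** 2, rel=1e-8)
        assert res.per_feature["p"].iloc[0] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_matches_statsmodels_type3(self):
        """Dual route: numpy implementation vs statsmodels anova_lm(typ=3)."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(11)
        n = 30
        group = rng.choice(["a", "b"], n)
        sex = rng.choice(["m", "f"], n)
        week = rng.normal(size=n)
        y = rng.normal(size=n) + (group == "b") + 0.5 * week
        m = _matrix(y)
        ph = _pheno(n, group, {"sex": sex, "week": week})
        res = type3_anova_screen(m, ph, top_n=1)
        df = pd.DataFrame({"y": y, "group": group, "sex": sex, "week": week})
        fit = ols("y ~ C(group, Sum) + C(sex, Sum) + week", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        for var, ref_row in (("group", "C(group, Sum)"), ("sex", "C(sex, Sum)"), ("week", "week")):
            mine = res.per_feature[res.per_feature.variable == var].iloc[0]
            assert mine["F"] == pytest.approx(ref.loc[ref_row, "F"], rel=1e-8)
            assert mine["p"] == pytest.approx(ref.loc[ref_row, "PR(>F)"], rel=1e-8)

    def test_type3_equals_type1_when_balanced_orthogonal(self):
        rng = np.random.default_rng(13)
        a = np.tile(["x", "y"], 10)
        b = np.repeat(["u", "v"], 10)
        y = rng.normal(size=20)
        m = _matrix(y)
        ph = _pheno(20, a, {"b": b})
        res = type3_anova_screen(m, ph, top_n=1)
        from statsmodels.formula.api import ols
        import statsmodels.api as sm

        fit = ols("y ~ C(a, Sum) + C(b, Sum)",
                  data=pd.DataFrame({"y": y, "a": a, "b": b})).fit()
        ref1 = sm.stats.anova_lm(fit, typ=1)
        f_a = res.per_feature[res.per_feature.variable == "group"]["F"].iloc[0]
        assert f_a == pytest.approx(ref1.loc["C(a, Sum)", "F"], rel=1e-8)

    def test_aliased_variables_rejected(self):
        rng = np.random.default_rng(1)
        n = 20
        group = np.tile(["a", "b"], n // 2)
        m = _matrix(rng.normal(size=(3, n)))
        ph = _pheno(n, group, {"dup": group.copy()})
        with pytest.raises(ValueError, match="aliased|collinear"):
            type3_anova_screen(m, ph, top_n=3)


class TestModeratedFit:
    @staticmethod
    def _null_fixture(units=40, n=12, seed=3):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(units, n)) * rng.uniform(0.5, 2.0, size=(units, 1))
        x = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        return y, x

    def test_zero_prior_df_equals_ordinary_t(self):
        y, x = self._null_fixture()
        tab = moderated_fit(y, x, 1, prior_df=0)
        # ordinary per-unit t oracle
        import statsmodels.api as sm

        for i in range(5):
            fit = sm.OLS(y[i], x).fit()
            assert tab["t"].iloc[i] == pytest.approx(fit.tvalues[1], abs=1e-10)

    def test_identical_variances_give_pooled_t(self):
        n = 10
        x = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        rng = np.random.default_rng(9)
        base = rng.normal(size=(1, n))
        # same residuals across units: shifts are absorbed by the intercept
        y = np.vstack([base + c for c in range(6)])
        tab = moderated_fit(y, x, 1)
        assert np.allclose(tab["t"], tab["t"].iloc[0])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(13)
        units, n = 500, 50
        y = rng.normal(size=(units, n))
        x = np.column_stack([np.ones(n), np.repeat([0, 1], n // 2)])
        tab = moderated_fit(y, x, 1)
        ks = stats.kstest(tab["p"], "uniform").statistic
        assert ks < 0.08

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma on the same fixture."""
        y, x = self._null_fixture(units=40, n=12, seed=42)
        y[:5] += 1.5 * x[:, 1]
        np.savetxt(tmp_path / "y.tsv", y, delimiter="\t")
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.table("{tmp_path}/y.tsv"))
        design <- cbind(1, rep(c(0,1), each=6))
        fit <- eBayes(lmFit(y, design))
        write.table(cbind(fit$coefficients[,2], fit$t[,2], fit$p.value[,2]),
                    "{tmp_path}/out.tsv", sep="\\t", col.names=FALSE, row.names=FALSE)
        """
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = np.loadtxt(tmp_path / "out.tsv")
        mine = moderated_fit(y, x, 1)
        np.testing.assert_allclose(mine["effect"], ref[:, 0], atol=1e-10)
        np.testing.assert_allclose(mine["t"], ref[:, 1], atol=1e-8)
        np.testing.assert_allclose(mine["p"], ref[:, 2], atol=1e-10)


def _scenario_modules(seed, module_shift=2.0):
    sc = simulate_mediation_phenotype(
        seed=seed, n_background=60, module_shift=module_shift
    )
    ms = compute_eigengenes(sc.matrix, sc.assignment)
    return sc, ms


class TestDiffModules:
    def test_planted_differential_module_detected(self):
        hits = 0
        for seed in range(5):
            sc, ms = _scenario_modules(seed)
            tab = diff_modules(ms, sc.phenotypes)
            hits += bool(tab.set_index("unit").loc["ME1", "significant"])
        assert hits >= 4

    def test_permuted_labels_mostly_null(self):
        false_hits = 0
        for seed in range(5):
            sc, ms = _scenario_modules(seed)
            rng = np.random.default_rng(seed + 100)
            data = sc.phenotypes.data.copy()
            data["group"] = rng.permutation(data["group"].to_numpy())
            ph = PhenotypeTable(data, "group", ["conf"])
            tab = diff_modules(ms, ph)
            false_hits += int(tab["significant"].sum())
        assert false_hits <= 1

    def test_confounder_explaining_shift(self):
        """A module shifted only through the confounder is significant without
        adjustment and null with it."""
        rng = np.random.default_rng(21)
        n = 120
        conf = rng.normal(size=n)
        group = (rng.uniform(size=n) < 1 / (1 + np.exp(-2.0 * conf))).astype(int)
        factor = 1.2 * conf + 0.6 * rng.normal(size=n)
        vals = np.vstack([0.8 * factor + 0.6 * rng.normal(size=n) for _ in range(30)])
        m = _matrix(vals)
        ms = compute_eigengenes(m, {f: "ME1" for f in m.feature_ids})
        df = pd.DataFrame(
            {"group": np.where(group == 1, "g1", "g0"), "conf": conf},
            index=m.sample_ids,
        )
        with_conf = diff_modules(ms, PhenotypeTable(df, "group", ["conf"]))
        without = diff_modules(ms, PhenotypeTable(df, "group", []))
        assert bool(without["significant"].iloc[0])
        assert not bool(with_conf["significant"].iloc[0])


class TestDiffFeaturesWithinModule:
    def test_recall_and_false_positives(self):
        rng = np.random.default_rng(17)
        n = 120
        group01 = np.repeat([0, 1], n // 2)
        shifted = np.vstack(
            [0.1 * group01 + 0.03 * rng.normal(size=n) + 0.5 for _ in range(30)]
        )
        flat = np.vstack([0.03 * rng.normal(size=n) + 0.5 for _ in range(20)])
        m = _matrix(np.vstack([shifted, flat]))
        ms = compute_eigengenes(m, {f: "ME1" for f in m.feature_ids})
        ph = _pheno(n, np.where(group01 == 1, "g1", "g0"))
        tab = diff_features_within_module(m, ms, "ME1", ph).set_index("unit")
        shifted_ids = [f"g{i}" for i in range(30)]
        flat_ids = [f"g{i}" for i in range(30, 50)]
        recall = tab.loc[shifted_ids, "significant"].mean()
        fp = int(tab.loc[flat_ids, "significant"].sum())
        assert recall >= 0.9
        assert fp <= 3

    def test_zero_difference_module_null(self):
        false_hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 80
            m = _matrix(rng.normal(size=(40, n)))
            ms = compute_eigengenes(m, {f: "ME1" for f in m.feature_ids})
            ph = _pheno(n, np.tile(["g0", "g1"], n // 2))
            tab = diff_features_within_module(m, ms, "ME1", ph)
            false_hits.append(int(tab["significant"].sum()))
        assert sum(h == 0 for h in false_hits) >= 4

    def test_effect_sign_convention(self):
        n = 40
        group01 = np.repeat([0, 1], n // 2)
        rng = np.random.default_rng(2)
        up = 1.0 * group01 + 0.1 * rng.normal(size=n)
        down = -1.0 * group01 + 0.1 * rng.normal(size=n)
        m = _matrix(np.vstack([up, down, rng.normal(size=n)]))
        ms = compute_eigengenes(m, {f: "ME1" for f in m.feature_ids})
        ph = _pheno(n, np.where(group01 == 1, "g1", "g0"))
        tab = diff_features_within_module(m, ms, "ME1", ph).set_index("unit")
        assert tab.loc["g0", "effect"] > 0  # up in the non-reference group
        assert tab.loc["g1", "effect"] < 0
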