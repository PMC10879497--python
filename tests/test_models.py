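"""Mixed-effects trajectory models, contrasts, FDR and KS statistics."""

import numpy as np
import pandas as pd
import pytest

from netaging.cohort import MONTH_DAYS
from netaging.models import (bh_fdr, fit_lme, ks_compare,
                             mass_univariate_lme, si_trajectory_analysis,
                             time_contrast)

import _oracles as oracle


def make_long(n_subjects, slope_per_day, intercept=2.0, re_sd=0.5,
              noise_sd=0.2, seed=0, factor=None, slope_b=None):
    """Balanced 3-visit longitudinal data with known fixed effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0, re_sd)
        level = ("A" if i < n_subjects // 2 else "B") if factor else None
        slope = slope_per_day if level in (None, "A") else slope_b
        for age in (365.0, 548.0, 730.0):
            a = age + rng.uniform(-14, 14)
            y = intercept + slope * a + b + rng.normal(0, noise_sd)
            row = dict(subject_id=f"s{i:03d}", age_days=a, y=y)
            if factor:
                row[factor] = level
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitLme:
    def test_balanced_zero_re_matches_ols(self):
        d = make_long(20, -0.001, re_sd=0.0, noise_sd=0.1, seed=1)
        res = fit_lme(d, "y")
        X = np.column_stack([np.ones(len(d)),
                             (d.age_days - d.age_days.mean()) / MONTH_DAYS])
        beta = np.linalg.lstsq(X, d.y.to_numpy(), rcond=None)[0]
        assert res.params.loc["intercept", "estimate"] == pytest.approx(
            beta[0], abs=1e-6)
        assert res.params.loc["age", "estimate"] == pytest.approx(
            beta[1], abs=1e-6)

    def test_residual_df(self):
        d = make_long(10, 0.0, factor="sex", slope_b=0.0)
        res = fit_lme(d, "y", factor="sex")
        assert res.df_resid == res.n_observations - 4
        # t = estimate / se identity
        t = res.params["estimate"] / res.params["se"]
        assert np.allclose(t, res.params["t"], atol=1e-8)

    def test_slope_reported_per_day_and_month(self):
        d = make_long(20, -0.001, seed=2)
        res = fit_lme(d, "y")
        age = res.params.loc["age"]
        assert age["estimate_per_day"] == pytest.approx(
            age["estimate"] / MONTH_DAYS)
        assert abs(age["estimate_per_day"] - (-0.001)) \
            <= 3 * age["se"] / MONTH_DAYS

    def test_factor_levels_validated(self):
        d = make_long(10, 0.0)
        d["sex"] = "F"
        with pytest.raises(ValueError, match="2 levels"):
            fit_lme(d, "y", factor="sex")

    def test_parameter_recovery_small(self):
        """Slope recovered within 3 SE in nearly all replicates (quick
        version of the acceptance-scale experiment)."""
        hits = 0
        for rep in range(20):
            d = make_long(30, -0.001, seed=100 + rep)
            res = fit_lme(d, "y")
            age = res.params.loc["age"]
            if abs(age["estimate_per_day"] - (-0.001)) \
                    <= 3 * age["se"] / MONTH_DAYS:
                hits += 1
        assert hits >= 18


class TestTimeContrast:
    def test_equal_slopes_recover_age_coefficient(self):
        d = make_long(24, -0.001, factor="sex", slope_b=-0.001, seed=3,
                      noise_sd=0.05)
        res = fit_lme(d, "y", factor="sex", reference="A")
        tc = time_contrast(res)
        inter = res.params.loc["age:sex[B]"]
        assert abs(inter["estimate"]) < 3 * inter["se"]
        assert tc["estimate"] == pytest.approx(
            res.params.loc["age", "estimate"]
            + 0.5 * inter["estimate"], abs=1e-12)

    def test_symmetric_slopes_cancel(self):
        d = make_long(40, 0.002, factor="sex", slope_b=-0.002, seed=4,
                      re_sd=0.1, noise_sd=0.05)
        res = fit_lme(d, "y", factor="sex", reference="A")
        tc = time_contrast(res)
        assert abs(tc["estimate_per_day"]) < 3 * tc["se"] / MONTH_DAYS

    def test_variance_matches_covariance_algebra(self):
        d = make_long(16, -0.001, factor="sex", slope_b=0.001, seed=5)
        res = fit_lme(d, "y", factor="sex", reference="A")
        tc = time_contrast(res)
        c = np.array([0.0, 1.0, 0.0, 0.5])
        var = c @ res.cov.to_numpy() @ c
        assert tc["se"] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_requires_interaction(self):
        d = make_long(10, 0.0)
        res = fit_lme(d, "y")
        with pytest.raises(ValueError, match="interaction"):
            time_contrast(res)


class TestBH:
    def test_worked_step_up(self):
        rej, q = bh_fdr([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert np.allclose(q, 0.04)
        assert rej.all()

    def test_all_equal_p(self):
        _, q = bh_fdr([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.random(m)
            rej, q = bh_fdr(p, alpha=0.05)
            rej_o, q_o = oracle.bh_stepup(p, alpha=0.05)
            assert np.array_equal(rej, rej_o)
            assert np.allclose(q, q_o, atol=1e-12)
        # q monotone in p after sorting, q >= p
        p = rng.random(50)
        _, q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestKS:
    def test_identical_samples_zero(self):
        s, _ = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s == 0.0

    def test_disjoint_supports_one(self):
        s, p = ks_compare([0.0, 0.1], [5.0, 6.0])
        assert s == 1.0

    def test_worked_example_third(self):
        s, _ = ks_compare([1, 2, 3], [2, 3, 4])
        assert s == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_matches_ecdf_enumeration_small_pairs(self):
        vals = [0.0, 0.5, 1.0, 2.0]
        rng = np.random.default_rng(0)
        for _ in range(100):
            na, nb = rng.integers(1, 7), rng.integers(1, 7)
            a = rng.choice(vals, na)
            b = rng.choice(vals, nb)
            s, _ = ks_compare(a, b)
            assert s == pytest.approx(oracle.ks_statistic(a, b), abs=1e-12)


class TestMassUnivariate:
    def test_null_units_controlled(self):
        rng = np.random.default_rng(6)
        frames = []
        for u in range(12):
            d = make_long(12, 0.0, seed=600 + u, re_sd=0.3)
            d["unit"] = f"u{u:02d}"
            frames.append(d)
        tab = pd.concat(frames).rename(columns={"y": "value"})
        out = mass_univariate_lme(tab, unit_col="unit")
        assert len(out) == 12
        assert out["q"].min() >= out["p"].min()
        assert out["significant_fdr"].sum() <= 1

    def test_strong_unit_detected(self):
        rng = np.random.default_rng(7)
        frames = []
        for u, slope in enumerate([0.0, 0.0, -0.004]):
            d = make_long(16, slope, seed=700 + u, re_sd=0.2, noise_sd=0.1)
            d["unit"] = f"u{u}"
            frames.append(d)
        tab = pd.concat(frames).rename(columns={"y": "value"})
        out = mass_univariate_lme(tab, unit_col="unit")
        assert bool(out.loc["u2", "significant_fdr"])
        assert out.loc["u2", "sign"] == -1.0


class TestSITrajectoryAnalysis:
    def _seg_table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, slope in (("X", -2.5e-4), ("Y", 0.0)):
            for i in range(8):
                b = rng.normal(0, 0.02)
                for age in (365.0, 548.0, 730.0):
                    a = age + rng.uniform(-14, 14)
                    si3 = 0.8 + slope * (a - 365.0) + b + rng.normal(0, 0.01)
                    rows.append(dict(
                        subject_id=f"{g}{i:02d}", sex="F" if i % 2 else "M",
                        cohort="C", group=g, timepoint_label="tp",
                        age_days=a, si3=si3, si_all=si3, excluded=False,
                        defined=True))
        return pd.DataFrame(rows)

    def test_group_slopes_recovered(self):
        rep = si_trajectory_analysis(self._seg_table(), outcome="si3")
        x = rep[(rep.analysis == "by_group") & (rep.stratum == "X")
                & (rep.term == "age")].iloc[0]
        y = rep[(rep.analysis == "by_group") & (rep.stratum == "Y")
                & (rep.term == "age")].iloc[0]
        assert x["estimate_per_day"] == pytest.approx(-2.5e-4, rel=0.3)
        assert x["p"] < 0.05
        assert abs(y["estimate_per_day"]) < 3 * y["se"] / MONTH_DAYS

    def test_subject_order_invariant(self):
        tab = self._seg_table(seed=3)
        a = si_trajectory_analysis(tab, outcome="si3")
        b = si_trajectory_analysis(tab.sample(frac=1.0, random_state=1),
                                   outcome="si3")
        pd.testing.assert_frame_equal(
            a.sort_values(["analysis", "stratum", "term"]).reset_index(drop=True),
            b.sort_values(["analysis", "stratum", "term"]).reset_index(drop=True),
            check_exact=False, atol=1e-8)

    def test_small_stratum_skipped_with_warning(self):
        tab = self._seg_table()
        tab = tab[~((tab.group == "Y") & (tab.subject_id > "Y01"))]
        with pytest.warns(UserWarning, match="fewer than"):
            si_trajectory_analysis(tab, outcome="si3")

    def test_excluded_subjects_dropped(self):
        tab = self._seg_table()
        flagged = tab.copy()
        flagged.loc[flagged.subject_id == "X00", "excluded"] = True
        rep_all = si_trajectory_analysis(tab, outcome="si3")
        rep_flagged = si_trajectory_analysis(flagged, outcome="si3")
        n_all = rep_all[rep_all.analysis == "overall"].iloc[0]["n_subjects"]
        n_fl = rep_flagged[rep_flagged.analysis == "overall"].iloc[0]["n_subjects"]
        assert n_fl == n_all - 1
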