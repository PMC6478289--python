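"""Mixed-ANOVA engine: oracle equivalence, contracts, cross-checks."""

import numpy as np
import pandas as pd
import pytest

import larvagrowth as lg
from larvagrowth.inference import (feature_anova, repeated_anova,
                                   size_dependence, anova_frame)
from larvagrowth.trajectory import Trajectory, TrajectoryTable


# ---------------------------------------------------------------------------
# independent brute-force oracle: Type III F from sums of squares


def _ols_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _type3_F(X, y, cols):
    """Classical fixed-effects Type III F for the given column block."""
    keep = [j for j in range(X.shape[1]) if j not in cols]
    rss_full = _ols_rss(X, y)
    mse = rss_full / (len(y) - X.shape[1])
    return (_ols_rss(X[:, keep], y) - rss_full) / len(cols) / mse


def _feature_frame(n_broods, pattern, sex_effect=0.0, plant_effect=0.0):
    """Balanced design replicating one residual pattern in every brood.

    Replication forces the between-brood variance of the residuals to be
    exactly zero, so REML lands on the boundary and the mixed ANOVA must
    agree with the fixed-effects oracle.
    """
    rows = []
    for b in range(n_broods):
        i = 0
        for sex in ("F", "M"):
            for host in ("host1", "host2"):
                for _ in range(len(pattern) // 4):
                    y = (10.0 + (sex_effect if sex == "F" else 0.0)
                         + (plant_effect if host == "host1" else 0.0)
                         + pattern[i])
                    rows.append(dict(individual_id=f"b{b}i{i}",
                                     brood_id=f"b{b}", sex=sex, host=host,
                                     response=y))
                    i += 1
    return pd.DataFrame(rows)


class TestFeatureAnovaOracle:
    def test_equals_fixed_effects_anova_on_zero_variance_design(self):
        rng = np.random.default_rng(7)
        pattern = rng.normal(0, 1, 8)
        df = _feature_frame(6, pattern, sex_effect=0.4, plant_effect=0.2)
        res = {r.factor: r for r in feature_anova(df, "response")}

        y = df["response"].to_numpy()
        X = np.column_stack([np.ones(len(y)),
                             np.where(df.sex == "F", 1.0, -1.0),
                             np.where(df.host == "host1", 1.0, -1.0)])
        for factor, col in (("sex", 1), ("plant", 2)):
            oracle = _type3_F(X, y, [col])
            assert res[factor].F == pytest.approx(oracle, rel=1e-7), factor
            assert res[factor].ndf == 1

    def test_r2_is_type3_share_of_total(self):
        rng = np.random.default_rng(3)
        df = _feature_frame(4, rng.normal(0, 1, 8), sex_effect=2.0)
        res = {r.factor: r for r in feature_anova(df, "response")}
        y = df["response"].to_numpy()
        X = np.column_stack([np.ones(len(y)),
                             np.where(df.sex == "F", 1.0, -1.0),
                             np.where(df.host == "host1", 1.0, -1.0)])
        ss_total = float(np.sum((y - y.mean()) ** 2))
        ss_sex = _ols_rss(X[:, [0, 2]], y) - _ols_rss(X, y)
        assert res["sex"].r2 == pytest.approx(ss_sex / ss_total, rel=1e-9)
        assert 0 <= res["sex"].r2 <= 1

    def test_cross_check_against_statsmodels_mixedlm(self):
        """Random-intercept fit agrees with an independent REML solver."""
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(11)
        rows = []
        for b in range(25):
            eff = rng.normal(0, 0.6)
            for i in range(8):
                sex = "F" if rng.random() < 0.5 else "M"
                host = "host1" if i < 6 else "host2"
                y = 5.0 + (0.8 if sex == "F" else 0) + eff + rng.normal(0, 1.0)
                rows.append(dict(individual_id=f"b{b}i{i}", brood_id=f"b{b}",
                                 sex=sex, host=host, response=y))
        df = pd.DataFrame(rows)
        res = {r.factor: r for r in feature_anova(df, "response")}
        sm_fit = smf.mixedlm(
            "response ~ C(sex, Sum) + C(host, Sum)", df,
            groups=df["brood_id"]).fit(reml=True)
        # statsmodels codes Sum levels so that the F coefficient is +1
        t_sm = sm_fit.tvalues["C(sex, Sum)[S.F]"]
        assert np.sqrt(res["sex"].F) == pytest.approx(abs(t_sm), rel=5e-3)

    def test_single_level_factor_rejected(self):
        df = _feature_frame(3, np.zeros(8), sex_effect=1.0)
        df["host"] = "host1"
        with pytest.raises(ValueError, match="plant"):
            feature_anova(df, "response")

    def test_unknown_response_rejected(self):
        df = _feature_frame(3, np.zeros(8))
        with pytest.raises(ValueError, match="response"):
            feature_anova(df, "nope")

    def test_pupal_mass_sex_effect_detected(self, default_population):
        """Females have heavier pupae; the mixed ANOVA must see it."""
        feats = lg.feature_table(default_population)
        res = {r.factor: r for r in feature_anova(feats, "pupal_mass")}
        means = feats.groupby("sex")["pupal_mass"].mean()
        assert means["F"] > means["M"]
        assert res["sex"].p < 1e-6
        assert res["sex"].F > 0 and 0 <= res["sex"].r2 <= 1


def _repeated_frame(n_broods, day_noise, sex_slope=0.0, sex_effect=0.0):
    """Repeated layout with residuals identical across individuals.

    Within a (sex, host) cell every individual shows the same day
    pattern, so brood and individual variance components are exactly
    zero and REML must collapse to the fixed-effects fit.
    """
    rows = []
    for b in range(n_broods):
        for i, (sex, host) in enumerate([("F", "host1"), ("F", "host2"),
                                         ("M", "host1"), ("M", "host2")]):
            for k, day in enumerate((2, 3, 4, 5)):
                y = (1.0 + (sex_effect if sex == "F" else 0.0)
                     + (sex_slope * day if sex == "F" else 0.0)
                     + day_noise[(0 if sex == "F" else 1, k)])
                rows.append(dict(individual_id=f"b{b}i{i}", brood_id=f"b{b}",
                                 sex=sex, host=host, day=day, value=y,
                                 measure="allometric", covariate_mass=30.0))
    return pd.DataFrame(rows)


class TestRepeatedAnova:
    def test_equals_fixed_effects_repeated_oracle_on_zero_variance(self):
        rng = np.random.default_rng(5)
        noise = {(s, k): rng.normal(0, 0.3) for s in (0, 1) for k in range(4)}
        df = _repeated_frame(5, noise, sex_effect=0.5, sex_slope=0.05)
        res = {r.factor: r for r in repeated_anova(df)}

        y = df["value"].to_numpy()
        sex = np.where(df.sex == "F", 1.0, -1.0)
        plant = np.where(df.host == "host1", 1.0, -1.0)
        day = df["day"].to_numpy(float) - df["day"].mean()
        X = np.column_stack([np.ones(len(y)), sex, day, plant,
                             sex * day, sex * plant])
        for factor, col in (("sex", 1), ("day", 2), ("plant", 3),
                            ("sex:day", 4), ("sex:plant", 5)):
            oracle = _type3_F(X, y, [col])
            assert res[factor].F == pytest.approx(oracle, rel=1e-7), factor

    def test_denominator_df_derived_from_larvae_not_measurements(self):
        pat = [0.0, 0.1, -0.05, 0.2]  # deliberately non-linear in day
        df = _repeated_frame(5, {(s, k): pat[k] for s in (0, 1)
                                 for k in range(4)}, sex_effect=0.2)
        n_larvae = df["individual_id"].nunique()
        n_obs = len(df)
        res = {r.factor: r for r in repeated_anova(df)}
        # between-larva factors: larvae minus the 4 between-design params
        for factor in ("sex", "plant", "sex:plant"):
            assert res[factor].ddf == n_larvae - 4
        for factor in ("day", "sex:day"):
            assert res[factor].ddf == n_obs - n_larvae - 2

    def test_single_day_rejected(self):
        df = _repeated_frame(4, {(s, k): 0.0 for s in (0, 1)
                                 for k in range(4)})
        with pytest.raises(ValueError, match="repeated"):
            repeated_anova(df[df.day == 2])

    def test_mixed_measures_rejected(self, small_population):
        recs = lg.rate_table(small_population)
        with pytest.raises(ValueError, match="measure"):
            repeated_anova(recs)

    def test_sex_detected_without_day_interaction(self, small_population):
        """A pure rate shift shows up as sex, not sex:day."""
        recs = lg.rate_table(small_population, measures=("allometric",))
        res = {r.factor: r for r in repeated_anova(recs, "allometric")}
        assert res["sex:day"].p > 0.001  # no interaction was generated
        assert res["sex"].ndf == 1
        assert all(np.isfinite(r.F) and r.F >= 0 for r in res.values())


def _cubic_table(g=0.3, n_per_sex=12, days=6):
    """Noise-free cubic trajectories with varying initial sizes."""
    trajs = []
    for s, sex in enumerate(("F", "M")):
        for i, c0 in enumerate(np.linspace(2.5, 3.8, n_per_sex)):
            masses = [(c0 + g * d) ** 3 for d in range(1, days + 1)]
            trajs.append(Trajectory(
                f"{sex}{i}", f"b{i % 4}", "host1", sex, 18.0, c0 ** 3,
                masses, masses[-1], masses[0] / 2))
    return TrajectoryTable(trajs)


class TestSizeDependence:
    def test_allometric_slope_zero_relative_negative_on_cubic_growth(self):
        recs = lg.rate_table(_cubic_table(),
                             measures=("relative", "allometric"))
        fits = size_dependence(recs, days=(2, 3))
        for f in fits:
            if f.measure == "allometric":
                assert abs(f.slope) < 1e-10, (f.measure, f.day, f.sex)
            else:
                assert f.slope < 0, (f.measure, f.day, f.sex)
                assert f.slope + 1.96 * f.slope_se < 0  # significantly so

    def test_too_few_points_rejected(self):
        recs = lg.rate_table(_cubic_table(n_per_sex=2),
                             measures=("allometric",))
        with pytest.raises(ValueError, match="3 points"):
            size_dependence(recs, days=(2,), measures=("allometric",))

    def test_fit_reports_sample_size(self):
        recs = lg.rate_table(_cubic_table(n_per_sex=10),
                             measures=("allometric",))
        fits = size_dependence(recs, days=(2,), measures=("allometric",))
        assert all(f.n == 10 for f in fits)


def test_anova_frame_shape(small_population):
    recs = lg.rate_table(small_population, measures=("allometric",))
    frame = anova_frame(repeated_anova(recs, "allometric"))
    assert list(frame.columns) == ["factor", "F", "ndf", "ddf", "p", "r2",
                                   "method"]
    assert list(frame["factor"]) == ["sex", "day", "plant", "sex:day",
                                     "sex:plant"]
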