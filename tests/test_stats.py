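"""Mixed ANOVA against independent oracles, effect sizes, Scheffe, Pearson."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_mixed_anova
from steptime.simulate import CohortDesign, generate_cohort_outcomes
from steptime.stats import MixedAnova, partial_eta_squared, pearson, scheffe_posthoc


def _long(y_g1, y_g2, groups=("SMT", "CTRL"), tests=("pre", "post")):
    rows = []
    for g, block in zip(groups, (y_g1, y_g2)):
        for i, (pre, post) in enumerate(block):
            pid = f"{g}{i}"
            rows.append({"participant_id": pid, "group": g, "test": tests[0], "y": pre})
            rows.append({"participant_id": pid, "group": g, "test": tests[1], "y": post})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_dv_gives_zero_f(self):
        df = _long(np.full((4, 2), 3.0), np.full((4, 2), 3.0))
        res = MixedAnova(df, "y").fit()
        assert all(e.F == 0.0 and e.eta_p2 == 0.0 for e in res.effects)

    def test_matches_sums_of_squares_oracle_on_integers(self):
        y1 = np.array([[3.0, 5.0], [4.0, 9.0]])
        y2 = np.array([[2.0, 3.0], [6.0, 5.0]])
        res = MixedAnova(_long(y1, y2), "y").fit()
        ref = oracle_mixed_anova(y1, y2)
        for eff in ("group", "test", "group x test"):
            assert res[eff].F == pytest.approx(ref[eff], rel=1e-12)
        assert res[eff].df_error == ref["df_error"]

    def test_matches_oracle_on_random_balanced_data(self, rng):
        for _ in range(25):
            n = rng.integers(3, 15)
            y1 = rng.normal(0, 3, (n, 2))
            y2 = rng.normal(0.5, 3, (n, 2))
            res = MixedAnova(_long(y1, y2), "y").fit()
            ref = oracle_mixed_anova(y1, y2)
            for eff in ("group", "test", "group x test"):
                assert res[eff].F == pytest.approx(ref[eff], rel=1e-9)

    def test_matches_pingouin_on_balanced_data(self, rng):
        pg = pytest.importorskip("pingouin")
        y1, y2 = rng.normal(0, 2, (12, 2)), rng.normal(1, 2, (12, 2))
        df = _long(y1, y2)
        res = MixedAnova(df, "y").fit()
        ref = pg.mixed_anova(
            data=df, dv="y", within="test", between="group", subject="participant_id"
        ).set_index("Source")
        assert res["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert res["test"].F == pytest.approx(ref.loc["test", "F"], rel=1e-9)
        assert res["group x test"].F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)
        assert res["group x test"].eta_p2 == pytest.approx(ref.loc["Interaction", "np2"], rel=1e-9)

    def test_planted_interaction_detected_and_recovered(self):
        # the interaction contrast (difference-in-differences of the cell
        # means) should estimate the planted SMT-post shift, covered by
        # +/- 2 SE at roughly the nominal rate, and be detected essentially
        # always at this effect size
        planted = 2.0
        detected = covered = 0
        n_rep = 60
        for seed in range(n_rep):
            d = CohortDesign(seed=seed, effect_correct_taps=planted)
            df, _ = generate_cohort_outcomes(d)
            data = MixedAnova.aggregate_trials(df, "correct_taps", unit="trial")
            res = MixedAnova(data, "correct_taps", subject="unit_id").fit()
            detected += res["group x test"].p < 0.05
            cm = res.cell_means
            did = (cm.loc["SMT", "post"] - cm.loc["SMT", "pre"]) - (
                cm.loc["CTRL", "post"] - cm.loc["CTRL", "pre"]
            )
            se = abs(did) / np.sqrt(res["group x test"].F)
            covered += abs(did - planted) <= 2 * se
        assert detected >= 0.95 * n_rep
        assert covered >= 0.85 * n_rep  # nominal ~95% coverage

    def test_trial_and_participant_units_agree_with_one_trial_each(self, rng):
        d = CohortDesign(n_per_group=6, trials_per_test=1, seed=8)
        df, _ = generate_cohort_outcomes(d)
        f = {}
        for unit in ("trial", "participant"):
            data = MixedAnova.aggregate_trials(df, "correct_taps", unit=unit)
            res = MixedAnova(data, "correct_taps", subject="unit_id").fit()
            f[unit] = res["group x test"].F
        assert f["trial"] == pytest.approx(f["participant"], rel=1e-9)

    def test_incomplete_unit_rejected(self):
        df = _long(np.ones((3, 2)), np.zeros((3, 2)))
        df = df.iloc[:-1]  # drop one post measurement
        with pytest.raises(ValueError, match="missing a within level"):
            MixedAnova(df, "y")

    def test_empty_cell_rejected(self):
        df = _long(np.ones((3, 2)), np.zeros((3, 2)))
        df = df[~((df.group == "CTRL") & (df.participant_id != "CTRL0"))]
        with pytest.raises(ValueError, match="fewer than 2 units"):
            MixedAnova(df, "y")

    def test_eta_identity_holds_on_fitted_results(self, rng):
        y1, y2 = rng.normal(0, 2, (8, 2)), rng.normal(1, 2, (8, 2))
        res = MixedAnova(_long(y1, y2), "y").fit()
        for e in res.effects:
            assert e.eta_p2 == pytest.approx(
                partial_eta_squared(e.F, e.df_effect, e.df_error), abs=1e-12
            )


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [
            (21.40, 1, 22, 0.493),
            (0.0, 1, 22, 0.0),
            (8.03, 1, 120, 0.063),
        ],
    )
    def test_known_values(self, F, df1, df2, expected):
        assert partial_eta_squared(F, df1, df2) == pytest.approx(expected, abs=5e-4)

    def test_negative_f_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 22)


class TestScheffe:
    @staticmethod
    def _tables(means):
        cm = pd.DataFrame(means, index=["SMT", "CTRL"], columns=["pre", "post"])
        cn = pd.DataFrame(12, index=["SMT", "CTRL"], columns=["pre", "post"])
        return cm, cn

    def test_identical_means_nothing_significant(self):
        cm, cn = self._tables([[5.0, 5.0], [5.0, 5.0]])
        out = scheffe_posthoc(cm, cn, ms_error=4.0, df_error=44)
        assert not out.significant.any()

    def test_huge_shift_is_significant(self):
        # one cell shifted by 10 pooled SDs
        cm, cn = self._tables([[5.0, 5.0 + 10 * 2.0], [5.0, 5.0]])
        out = scheffe_posthoc(cm, cn, ms_error=4.0, df_error=44)
        hit = out[(out.cell_a == "SMT:post") | (out.cell_b == "SMT:post")]
        assert hit.significant.all()

    def test_conservative_relative_to_pairwise_t(self, rng):
        from scipy import stats as sps

        for _ in range(20):
            cm, cn = self._tables(rng.normal(0, 1, (2, 2)))
            ms, dfe = 1.0, 44
            out = scheffe_posthoc(cm, cn, ms_error=ms, df_error=dfe)
            for row in out.itertuples():
                t2 = row.mean_diff**2 / (ms * (2 / 12))
                p_t = float(sps.f.sf(t2, 1, dfe))
                assert row.p >= p_t - 1e-12

    def test_single_cell_rejected(self):
        cm = pd.DataFrame([[1.0]], index=["SMT"], columns=["pre"])
        cn = pd.DataFrame([[5]], index=["SMT"], columns=["pre"])
        with pytest.raises(ValueError, match="2 cells"):
            scheffe_posthoc(cm, cn, 1.0, 10)

    def test_results_object_scheffe_detects_planted_cell_shift(self):
        d = CohortDesign(seed=2, effect_correct_taps=6.0)
        df, _ = generate_cohort_outcomes(d)
        data = MixedAnova.aggregate_trials(df, "correct_taps", unit="participant")
        res = MixedAnova(data, "correct_taps", subject="unit_id").fit()
        out = res.scheffe()
        row = out[(out.cell_a == "SMT:pre") & (out.cell_b == "SMT:post")]
        assert row.significant.all()


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_samples_near_zero(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        r, _ = pearson(x, y)
        assert abs(r) < 0.05

    def test_symmetry(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert pearson(x, y)[0] == pearson(y, x)[0]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson(np.ones(10), np.arange(10.0))
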