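"""Scalar statistics: published-summary checks and independent oracles."""

import numpy as np
import pytest
import scipy.stats as st

from assrshift.stats import (
    GroupSummary,
    chi_square,
    cohens_d,
    pla_effect_size,
    rmanova_2x2,
    spearman,
    watson_williams,
    welch_t,
)


class TestWelchT:
    @pytest.mark.parametrize(
        "s1, s2, t_exp, df_exp",
        [
            # demographic summaries of the two diagnostic groups
            (GroupSummary(60, 15.40, 2.78), GroupSummary(68, 13.54, 2.61), 3.88, 121.66),
            (GroupSummary(66, 36.95, 10.26), GroupSummary(68, 34.94, 12.26), 1.03, 129.22),
        ],
    )
    def test_published_summaries(self, s1, s2, t_exp, df_exp):
        # summaries are printed rounded to 2 d.p., so the recomputed statistic
        # can differ from the printed one by a unit in the last digit
        res = welch_t(s1, s2)
        assert res["t"] == pytest.approx(t_exp, abs=0.01)
        assert res["df"] == pytest.approx(df_exp, abs=0.01)

    def test_equal_summaries_give_zero(self):
        res = welch_t(GroupSummary(10, 5.0, 1.0), GroupSummary(12, 5.0, 2.0))
        assert res["t"] == 0.0

    def test_raw_equals_summaries(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 2, 55)
        raw = welch_t(x, y)
        summ = welch_t(GroupSummary.from_sample(x), GroupSummary.from_sample(y))
        assert raw["t"] == pytest.approx(summ["t"], abs=1e-12)
        assert raw["df"] == pytest.approx(summ["df"], abs=1e-12)

    def test_zero_variance_both_groups_errors(self):
        with pytest.raises(ValueError):
            welch_t(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 2.0, 0.0))


class TestChiSquare:
    def test_sex_table(self):
        res = chi_square([[30, 36], [35, 33]])
        assert round(res["chi2"], 2) == 0.49
        assert res["df"] == 1

    def test_handedness_table(self):
        res = chi_square([[2, 59, 0], [3, 57, 1]])
        assert round(res["chi2"], 2) == 1.23
        assert res["df"] == 2

    def test_proportional_rows_give_zero(self):
        res = chi_square([[10, 20, 30], [20, 40, 60]])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self, rng):
        tbl = rng.integers(5, 50, size=(3, 4))
        base = chi_square(tbl)["chi2"]
        assert chi_square(tbl[::-1])["chi2"] == pytest.approx(base)
        assert chi_square(tbl[:, ::-1])["chi2"] == pytest.approx(base)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [1, 2]])


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(GroupSummary(10, 3.0, 1.0), GroupSummary(10, 3.0, 2.0)) == 0.0

    def test_published_plf_summaries(self):
        # cluster-level PLF group summaries; printed d from unrounded data is 0.703
        d = cohens_d(GroupSummary(66, 0.330, 0.127), GroupSummary(68, 0.252, 0.096))
        assert d == pytest.approx(0.703, abs=0.02)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(0, 1.3, 25)
        y = rng.normal(0.4, 0.9, 31)
        pooled = np.sqrt(((24) * x.var(ddof=1) + (30) * y.var(ddof=1)) / 54)
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / pooled, abs=1e-12)


class TestPlaEffectSize:
    def test_z_transform_of_reference_sample(self, rng):
        nc = rng.normal(0.2, 0.3, 50)
        z = (nc - nc.mean()) / nc.std(ddof=1)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_identical_distributions_near_zero(self, rng):
        ds = [
            pla_effect_size(rng.normal(0, 0.25, 60), rng.normal(0, 0.25, 60))
            for _ in range(50)
        ]
        assert abs(np.mean(ds)) < 0.1

    def test_known_offset_recovered(self, rng):
        # offset 0.5 rad at common spread 0.25 -> d = 2 by construction
        ds = [
            pla_effect_size(rng.normal(0, 0.25, 200), rng.normal(0.5, 0.25, 200))
            for _ in range(200)
        ]
        assert np.mean(np.abs(ds)) == pytest.approx(2.0, abs=0.15)


class TestWatsonWilliams:
    def test_identical_concentrated_samples(self):
        a = np.full(20, 0.3) + np.linspace(-0.01, 0.01, 20)
        res = watson_williams(a, a.copy())
        assert res["F"] == pytest.approx(0.0, abs=1e-6)
        assert res["p"] > 0.99

    def test_separated_von_mises_rejects(self, rng):
        rejections = 0
        for _ in range(20):
            a = rng.vonmises(0.0, 5.0, 30)
            b = rng.vonmises(np.pi / 2, 5.0, 30)
            if watson_williams(a, b)["p"] < 0.001:
                rejections += 1
        assert rejections == 20

    def test_agrees_with_permutation_oracle(self, rng):
        """Decision at alpha=0.05 matches a permutation test on the circular
        mean difference in >=95% of simulated datasets."""

        def perm_test(a, b, n_perm=400):
            def statistic(x, y):
                return np.abs(np.angle(np.exp(1j * x).mean() * np.exp(-1j * y).mean()))

            obs = statistic(a, b)
            pooled = np.concatenate([a, b])
            count = 0
            for _ in range(n_perm):
                rng.shuffle(pooled)
                if statistic(pooled[: a.size], pooled[a.size:]) >= obs:
                    count += 1
            return (1 + count) / (1 + n_perm)

        agree = 0
        n_sets = 40
        for i in range(n_sets):
            shift = rng.uniform(0, 0.8)
            a = rng.vonmises(0.0, 4.0, 25)
            b = rng.vonmises(shift, 4.0, 25)
            d1 = watson_williams(a, b)["p"] < 0.05
            d2 = perm_test(a, b) < 0.05
            agree += d1 == d2
        assert agree / n_sets >= 0.95

    def test_low_concentration_warns_not_errors(self, rng):
        res = watson_williams(rng.uniform(-np.pi, np.pi, 30), rng.uniform(-np.pi, np.pi, 30))
        assert res["warning"] is not None


class TestSpearman:
    def test_monotone_relationships(self, rng):
        x = rng.normal(0, 1, 30)
        assert spearman(x, np.exp(x))["rho"] == pytest.approx(1.0)
        assert spearman(x, -(x**3))["rho"] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float) + 0.3 * x
        rho = spearman(x, y)["rho"]
        rx, ry = st.rankdata(x), st.rankdata(y)  # average ranks
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_bonferroni_alpha(self, rng):
        x = rng.normal(size=20)
        res = spearman(x, x + rng.normal(size=20), bonferroni_m=5)
        assert res["alpha"] == 0.05 / 5

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))


def _rmanova_oracle(rest, task, groups):
    """Brute-force cell-means / error-SS mixed ANOVA for the 2x2 design."""
    labels = np.unique(groups)
    y = np.stack([rest, task], axis=1)
    n, k = y.shape
    grand = y.mean()
    ss = {}
    # full enumeration over cells and subjects
    ss_cells = 0.0
    for li, lab in enumerate(labels):
        for s in range(k):
            cell = y[groups == lab, s]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
    gm = {lab: y[groups == lab].mean() for lab in labels}
    sm = {s: y[:, s].mean() for s in range(k)}
    ss["group"] = sum(k * (groups == lab).sum() * (gm[lab] - grand) ** 2 for lab in labels)
    ss["state"] = sum(n * (sm[s] - grand) ** 2 for s in range(k))
    ss["inter"] = ss_cells - ss["group"] - ss["state"]
    subj_mean = y.mean(axis=1)
    ss["subj"] = sum(
        k * ((subj_mean[groups == lab] - gm[lab]) ** 2).sum() for lab in labels
    )
    ss["total"] = ((y - grand) ** 2).sum()
    ss["err"] = ss["total"] - ss_cells - ss["subj"]
    df2 = n - 2
    return (
        (ss["group"] / 1) / (ss["subj"] / df2),
        (ss["state"] / 1) / (ss["err"] / df2),
        (ss["inter"] / 1) / (ss["err"] / df2),
    )


class TestRmanova:
    def test_equal_states_kill_state_effects(self, rng):
        vals = rng.normal(0, 1, 12)
        groups = np.array(["A"] * 6 + ["B"] * 6)
        res = rmanova_2x2(vals, vals.copy(), groups)
        assert res.F_state == pytest.approx(0.0, abs=1e-12)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_fixed_dataset(self):
        # constructed 8-subject dataset
        rest = np.array([1.0, 2.0, 1.5, 2.5, 3.0, 2.8, 3.3, 2.9])
        task = np.array([1.2, 2.5, 1.1, 2.9, 2.1, 2.0, 2.6, 2.2])
        groups = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])
        res = rmanova_2x2(rest, task, groups)
        fg, fs, fi = _rmanova_oracle(rest, task, groups)
        assert res.F_group == pytest.approx(fg, abs=1e-10)
        assert res.F_state == pytest.approx(fs, abs=1e-10)
        assert res.F_interaction == pytest.approx(fi, abs=1e-10)
        assert res.df2 == 6

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(5):
            n = 14
            rest = rng.normal(0, 1, n)
            task = rest + rng.normal(0.3, 0.5, n)
            groups = np.array(["A"] * 6 + ["B"] * 8)
            res = rmanova_2x2(rest, task, groups)
            fg, fs, fi = _rmanova_oracle(rest, task, groups)
            assert res.F_group == pytest.approx(fg, rel=1e-10)
            assert res.F_state == pytest.approx(fs, rel=1e-10)
            assert res.F_interaction == pytest.approx(fi, rel=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 20
        rest = rng.normal(0, 1, n)
        task = rest + rng.normal(0.4, 0.6, n)
        groups = np.array(["A"] * 9 + ["B"] * 11)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), 2),
            "state": ["rest", "task"] * n,
            "group": np.repeat(groups, 2),
            "y": np.stack([rest, task], axis=1).ravel(),
        })
        aov = pingouin.mixed_anova(df, dv="y", within="state", between="group",
                                   subject="subject")
        res = rmanova_2x2(rest, task, groups)
        assert res.F_group == pytest.approx(
            float(aov.loc[aov.Source == "group", "F"].iloc[0]), rel=1e-8
        )
        assert res.F_state == pytest.approx(
            float(aov.loc[aov.Source == "state", "F"].iloc[0]), rel=1e-8
        )
        assert res.F_interaction == pytest.approx(
            float(aov.loc[aov.Source == "Interaction", "F"].iloc[0]), rel=1e-8
        )

    def test_pure_interaction_construction(self, rng):
        n = 16
        groups = np.array(["A"] * 8 + ["B"] * 8)
        base = rng.normal(0, 0.1, n)
        delta = np.where(groups == "A", 1.0, -1.0)
        rest = base
        task = base + delta
        res = rmanova_2x2(rest, task, groups)
        assert res.F_state == pytest.approx(0.0, abs=1e-8 * res.F_interaction)
        assert res.F_interaction > 100
        assert res.post_hoc is not None
        assert res.post_hoc["alpha"] == 0.05 / 4

    def test_missing_state_errors(self):
        with pytest.raises(ValueError):
            rmanova_2x2(np.ones(4), np.ones(3), np.array(["A", "A", "B", "B"]))
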