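"""Statistical battery: t tests, residualization, FDR/Bonferroni families,
demographics, and score correlations against direct-formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reliafc.reliability import FilteredConnectome
from reliafc.stats import (
    demographics_table,
    edgewise_compare,
    nodewise_compare,
    residualize,
    score_correlation,
    two_sample_t,
)


def covariate_frame(n, rng, group=None):
    frame = pd.DataFrame(
        {
            "age": rng.normal(72, 7, n),
            "gender": rng.choice(["M", "F"], n),
            "education": rng.normal(12, 3, n),
            "mean_fd": np.abs(rng.normal(0.11, 0.05, n)),
            "mmse": rng.normal(28, 1.4, n),
        }
    )
    if group is not None:
        frame["group"] = group
    return frame


class TestTwoSampleT:
    def test_identical_groups_null(self):
        a = np.array([1.0, 2.0, 5.0])
        t, p = two_sample_t(a, a.copy())
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_pooled_oracle(self):
        # {1,2,3} vs {4,5,6}: pooled sd 1, se sqrt(2/3), t = -3/se
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346141747673, abs=1e-12)
        assert p == pytest.approx(0.021311641128756713, abs=1e-9)

    def test_summary_equivalent_mmse_moments(self):
        # samples constructed to match the published MMSE group moments
        # (27.52 +/- 1.44, n=25 vs 28.33 +/- 1.34, n=51); the printed
        # P = 0.019 came from raw data so only the range is pinned
        def exact_sample(mean, sd, n, rng):
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        rng = np.random.default_rng(0)
        a = exact_sample(27.52, 1.44, 25, rng)
        b = exact_sample(28.33, 1.34, 51, rng)
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(-2.415960650070345, abs=1e-9)
        assert 0.01 < p < 0.03

    def test_welch_differs_under_heteroscedasticity(self, rng):
        a = rng.normal(0, 5, 12)
        b = rng.normal(0.5, 0.5, 40)
        _, p_student = two_sample_t(a, b, "student")
        _, p_welch = two_sample_t(a, b, "welch")
        assert p_student != p_welch

    def test_zero_variance_cases(self):
        assert two_sample_t([1, 1, 1], [1.0, 1, 1]) == (0.0, 1.0)
        with pytest.raises(ValueError, match="unequal means"):
            two_sample_t([1, 1, 1], [2.0, 2, 2])


class TestResidualize:
    def test_perfect_fit_residuals_zero(self, rng):
        cov = covariate_frame(40, rng)
        values = 2.0 * cov["age"].to_numpy()
        assert np.abs(residualize(values, cov)).max() < 1e-10

    def test_idempotence(self, rng):
        cov = covariate_frame(76, rng)
        values = rng.standard_normal(76)
        once = residualize(values, cov)
        twice = residualize(once, cov)
        np.testing.assert_allclose(once, twice, atol=1e-10)
        assert abs(once.mean()) < 1e-12

    def test_null_regression_low_r2(self, rng):
        cov = covariate_frame(76, rng)
        values = rng.standard_normal(76)
        resid = residualize(values, cov)
        r2 = 1 - (resid**2).sum() / ((values - values.mean()) ** 2).sum()
        assert r2 < 0.15  # 4 regressors on 76 independent points

    def test_singular_design_names_column(self, rng):
        cov = covariate_frame(30, rng)
        cov["education"] = 12.0  # constant -> collinear with the intercept
        with pytest.raises(ValueError, match="education"):
            residualize(rng.standard_normal(30), cov)


def make_connectomes(values, names, prefix, group="g"):
    """Wrap an [n_subjects x p x p] stack as FilteredConnectome objects."""
    out = []
    for k, w in enumerate(values):
        out.append(
            FilteredConnectome(
                values=w, subject_id=f"{prefix}{k}", group=group,
                retained_edge_count=int((w != 0).sum() // 2), region_names=names,
            )
        )
    return out


def random_stack(n, p, rng, shift=0.0, node=None):
    stack = []
    for _ in range(n):
        w = np.abs(rng.normal(0.3, 0.1, (p, p)))
        w = (w + w.T) / 2
        if node is not None:
            w[node, :] += shift
            w[:, node] += shift
        np.fill_diagonal(w, 0.0)
        stack.append(w)
    return stack


class TestEdgewiseCompare:
    NAMES = tuple("abcdef")

    def test_brute_force_bh_semantics(self):
        # Benjamini-Hochberg by definition on a hand list
        pvals = np.array([0.001, 0.02, 0.03, 0.5])
        m = len(pvals)
        order = np.sort(pvals)
        passing = order[order <= (np.arange(1, m + 1) / m) * 0.05]
        threshold = passing.max()
        assert (pvals <= threshold).sum() == 3
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        assert reject.sum() == 3  # library agrees with the definition

    def test_null_and_planted_edges(self, rng):
        p = len(self.NAMES)
        a = make_connectomes(random_stack(12, p, rng), self.NAMES, "a")
        b_stack = random_stack(14, p, rng, shift=0.8, node=0)
        b = make_connectomes(b_stack, self.NAMES, "b")
        cov_a = covariate_frame(12, rng)
        cov_b = covariate_frame(14, rng)
        table = edgewise_compare(a, b, cov_a, cov_b)
        assert len(table) == p * (p - 1) // 2
        sig = table[table["fdr_significant"]]
        assert len(sig) > 0
        assert (sig["i"] == 0).all()  # only node-0 edges were shifted
        # flags consistent with the BH threshold reported
        thr = table.attrs["bh_threshold"]
        testable = table["testable"]
        np.testing.assert_array_equal(
            table.loc[testable, "fdr_significant"],
            table.loc[testable, "p"] <= thr,
        )

    def test_untestable_edges_leave_family(self, rng):
        p = len(self.NAMES)
        stack_a = random_stack(8, p, rng)
        stack_b = random_stack(8, p, rng)
        for w in stack_a + stack_b:  # silence edge (0, 1) everywhere
            w[0, 1] = w[1, 0] = 0.0
        a = make_connectomes(stack_a, self.NAMES, "a")
        b = make_connectomes(stack_b, self.NAMES, "b")
        table = edgewise_compare(a, b, covariate_frame(8, rng), covariate_frame(8, rng))
        row = table[(table["i"] == 0) & (table["j"] == 1)].iloc[0]
        assert not row["testable"] and np.isnan(row["p"])
        assert table.attrs["family_size"] == p * (p - 1) // 2 - 1
        assert table.attrs["untestable_edges"] == 1


class TestNodewiseCompare:
    NAMES = tuple("abcdefgh")

    def test_identical_groups_nothing_significant(self, rng):
        p = len(self.NAMES)
        stack = random_stack(10, p, rng)
        a = make_connectomes(stack, self.NAMES, "a")
        b = make_connectomes([w.copy() for w in stack], self.NAMES, "b")
        cov = covariate_frame(10, rng)
        table = nodewise_compare(a, b, cov, cov.copy())
        assert len(table) == p
        assert not table["bonferroni_significant"].any()

    def test_bonferroni_flag_definitional(self, rng):
        p = len(self.NAMES)
        a = make_connectomes(random_stack(10, p, rng), self.NAMES, "a")
        b = make_connectomes(random_stack(10, p, rng, shift=0.5, node=2),
                             self.NAMES, "b")
        table = nodewise_compare(a, b, covariate_frame(10, rng),
                                 covariate_frame(10, rng))
        for _, row in table.iterrows():
            if row["testable"]:
                assert row["bonferroni_significant"] == (row["p"] < 0.05 / p)

    def test_planted_node_detected_and_fwer_controlled(self):
        # A strong shift concentrated on one node's edges (many-SD in its
        # degree, sub-threshold spillover of one edge per other node): the
        # planted node is flagged, the rest stay at familywise-error level.
        p = 20
        names = tuple(f"r{k}" for k in range(p))
        hits, false_any = 0, 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = make_connectomes(random_stack(12, p, rng), names, "a")
            b = make_connectomes(random_stack(12, p, rng, shift=0.05, node=3),
                                 names, "b")
            table = nodewise_compare(a, b, covariate_frame(12, rng),
                                     covariate_frame(12, rng))
            flags = table["bonferroni_significant"].to_numpy()
            hits += flags[3]
            false_any += flags[np.arange(p) != 3].any()
        assert hits >= int(0.9 * n_seeds)
        assert false_any / n_seeds <= 0.10


class TestScoreCorrelation:
    def test_self_correlation(self, rng):
        x = rng.standard_normal(20)
        r, p = score_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_direct_formula_oracle(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        r, p = score_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        t = r_direct * np.sqrt(28 / (1 - r_direct**2))
        p_direct = 2 * sps.t.sf(abs(t), 28)
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert p == pytest.approx(p_direct, abs=1e-12)

    def test_constant_input_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            score_correlation(np.ones(10), rng.standard_normal(10))


class TestDemographics:
    def _frame(self, male_a, female_a, male_b, female_b, rng):
        rows = []
        for group, males, females in (("aMCI", male_a, female_a),
                                      ("NC", male_b, female_b)):
            n = males + females
            frame = covariate_frame(n, rng, group=group)
            frame["gender"] = ["M"] * males + ["F"] * females
            rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    def test_published_gender_table_chi_square(self, rng):
        # 17/8 vs 26/25: Pearson chi-square without continuity correction,
        # checked against a by-definition expected-count computation
        table = demographics_table(self._frame(17, 8, 26, 25, rng))
        row = table[table["covariate"] == "gender"].iloc[0]
        obs = np.array([[17, 8], [26, 25]], float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert row["statistic"] == pytest.approx(chi2, abs=1e-12)
        assert row["p"] == pytest.approx(sps.chi2.sf(chi2, 1), abs=1e-12)
        assert row["p"] == pytest.approx(0.160, abs=0.001)

    def test_identical_compositions_all_null(self, rng):
        base = covariate_frame(20, rng)
        frame = pd.concat(
            [base.assign(group="aMCI"), base.assign(group="NC")],
            ignore_index=True,
        )
        table = demographics_table(frame)
        for _, row in table.iterrows():
            assert row["p"] == pytest.approx(1.0)
            assert row["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_two_by_two_zero_statistic(self, rng):
        table = demographics_table(self._frame(10, 10, 10, 10, rng))
        row = table[table["covariate"] == "gender"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_gender_margin_rejected(self, rng):
        with pytest.raises(ValueError, match="expected count 0"):
            demographics_table(self._frame(10, 0, 12, 0, rng))
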