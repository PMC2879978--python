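import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from reaim.stats import (
    DegenerateTableError,
    InsufficientDataError,
    chi_square_phi2,
    representativeness_phi2,
    rm_anova_two_timepoints,
    summarize,
)


# ---------------------------------------------------------------------------
# independent oracles


def chi2_by_hand(table):
    """Pearson chi-square by direct expansion of sum((O-E)^2 / E)."""
    t = np.asarray(table, dtype=float)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    n = t.sum()
    expected = np.outer(rows, cols) / n
    return float(((t - expected) ** 2 / expected).sum())


def mixed_anova_by_hand(baseline, followup, labels):
    """Two-timepoint mixed-ANOVA sums of squares from first principles:
    cell means, subject means and unweighted marginal means, with the
    harmonic mean as the effective cell size (unweighted-means / Type III
    convention)."""
    y = np.column_stack([baseline, followup])
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()), key=str)
    g = len(groups)
    cell = np.array([[y[labels == grp, t].mean() for t in (0, 1)]
                     for grp in groups])               # M_jt
    group_mean = cell.mean(axis=1)                     # M_j.
    time_mean = cell.mean(axis=0)                      # unweighted T_t
    grand = time_mean.mean()
    sizes = np.array([(labels == grp).sum() for grp in groups])
    n_h = g / (1.0 / sizes).sum()

    ss_time = n_h * g * ((time_mean - grand) ** 2).sum()
    ss_inter = n_h * ((cell - group_mean[:, None] - time_mean[None, :]
                       + grand) ** 2).sum()
    subj_mean = y.mean(axis=1)
    ss_err = 0.0
    for j, grp in enumerate(groups):
        sel = labels == grp
        resid = (y[sel] - subj_mean[sel][:, None] - cell[j][None, :]
                 + group_mean[j])
        ss_err += (resid ** 2).sum()
    return ss_time, ss_inter, ss_err


# ---------------------------------------------------------------------------
# chi-square / squared Cramer phi


class TestChiSquarePhi2:
    def test_completion_by_sex_2x2(self):
        """Completer/non-completer by sex: weak but significant association
        (women complete the 12-week phase less often than men)."""
        res = chi_square_phi2([[993, 335], [267, 52]])
        assert res.phi_c2 == pytest.approx(0.007, abs=5e-4)
        assert res.p_value == pytest.approx(0.001, abs=5e-4)
        assert res.df == 1

    def test_independent_table_gives_zero(self):
        res = chi_square_phi2([[50, 50], [50, 50]])
        assert res.chi2 == 0.0
        assert res.phi_c2 == 0.0

    def test_3x2_matches_hand_expansion(self):
        table = [[10, 0], [0, 10], [5, 5]]
        res = chi_square_phi2(table)
        assert res.chi2 == pytest.approx(chi2_by_hand(table), rel=1e-12)
        assert res.phi_c2 == pytest.approx(res.chi2 / (30 * 1), rel=1e-12)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_phi2([[0, 0], [3, 4]])

    @given(st.lists(st.lists(st.integers(0, 200), min_size=2, max_size=5),
                    min_size=2, max_size=5).map(
                        lambda rows: [r[:min(map(len, rows))] for r in rows]))
    @settings(derandomize=True, max_examples=300)
    def test_phi2_bounded_and_classical_for_2x2(self, table):
        t = np.asarray(table)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            return
        res = chi_square_phi2(t)
        assert 0.0 <= res.phi_c2 <= 1.0
        if t.shape == (2, 2):
            assert res.phi_c2 == pytest.approx(res.chi2 / t.sum(), rel=1e-12)


class TestRepresentativeness:
    def test_perfectly_representative_is_zero(self):
        res = representativeness_phi2([541, 459], [0.541, 0.459], 10000)
        assert res.phi_c2 == pytest.approx(0.0, abs=1e-12)
        assert res.convention_dependent

    def test_matches_direct_table_construction(self):
        """All enrollment in one of two equal-mass categories: the result
        equals chi-square on the explicitly built 2x2 table."""
        res = representativeness_phi2([20, 0], [0.5, 0.5], 100)
        direct = chi_square_phi2([[20, 0], [30, 50]])
        assert res.phi_c2 == pytest.approx(direct.phi_c2, rel=1e-12)

    def test_sex_margins_report_as_computed(self):
        """The enrolled-vs-eligible sex construction yields whatever value
        the convention implies; it is flagged convention-dependent."""
        res = representativeness_phi2([1561, 391], [0.541, 0.459], 32878)
        direct = chi_square_phi2([[1561, 391],
                                  [0.541 * 32878 - 1561, 0.459 * 32878 - 391]])
        assert res.phi_c2 == pytest.approx(direct.phi_c2, rel=1e-12)
        assert res.convention_dependent

    def test_zero_mass_category_with_enrollment_rejected(self):
        with pytest.raises(ValueError, match="zero eligible mass"):
            representativeness_phi2([5, 5], [1.0, 0.0], 100)


# ---------------------------------------------------------------------------
# two-timepoint repeated-measures / mixed ANOVA


class TestRmAnova:
    def test_identical_vectors_no_change(self):
        x = np.array([200.0, 215.0, 230.0, 250.0, 180.0])
        res = rm_anova_two_timepoints(x, x)
        assert res.ss_time == 0.0
        assert res.eta2_time == 0.0

    def test_paired_t_equivalence(self):
        rng = np.random.default_rng(42)
        base = rng.normal(220, 30, size=10)
        follow = base + rng.normal(-12, 8, size=10)
        res = rm_anova_two_timepoints(base, follow)
        t, _ = sps.ttest_rel(follow, base)
        assert res.f_time == pytest.approx(t**2, rel=1e-10)
        assert res.eta2_time == pytest.approx(t**2 / (t**2 + 9), rel=1e-10)

    def test_saturated_interaction(self):
        """Constant within-group changes shifted between groups: all
        change variance is interaction."""
        base = np.array([200.0, 210.0, 220.0, 300.0, 310.0, 320.0])
        follow = base + np.array([-10.0, -10.0, -10.0, -20.0, -20.0, -20.0])
        res = rm_anova_two_timepoints(base, follow, list("aaabbb"))
        assert res.eta2_interaction == 1.0

    def test_fully_degenerate_data_flags(self):
        x = np.array([5.0, 5.0, 5.0])
        res = rm_anova_two_timepoints(x, x)
        assert res.degenerate
        assert res.eta2_time == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            rm_anova_two_timepoints([1.0, 2.0], [1.5, 2.5])

    def test_singleton_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            rm_anova_two_timepoints([1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                                    ["a", "a", "b"])

    def test_missing_pairs_dropped(self):
        base = np.array([200.0, np.nan, 220.0, 240.0, 260.0])
        follow = np.array([190.0, 210.0, np.nan, 230.0, 240.0])
        res = rm_anova_two_timepoints(base, follow)
        assert res.n_subjects == 3

    @pytest.mark.parametrize("n_groups", [1, 2, 3])
    def test_matches_first_principles_decomposition(self, n_groups):
        """Random small fixtures: SS match the cell-mean/subject-mean
        brute-force decomposition to 1e-9 relative."""
        rng = np.random.default_rng(7 + n_groups)
        for _ in range(25):
            n = int(rng.integers(2 * max(n_groups, 2), 13))
            labels = rng.integers(0, n_groups, size=n)
            # guarantee >= 2 per group
            labels[:2 * n_groups] = np.repeat(np.arange(n_groups), 2)
            base = rng.normal(220, 30, size=n)
            follow = base + rng.normal(-10, 9, size=n) + 3.0 * labels
            res = rm_anova_two_timepoints(base, follow,
                                          labels if n_groups > 1 else None)
            lab = labels if n_groups > 1 else np.zeros(n, dtype=int)
            ss_t, ss_i, ss_e = mixed_anova_by_hand(base, follow, lab)
            assert res.ss_time == pytest.approx(ss_t, rel=1e-9, abs=1e-12)
            if n_groups > 1:
                assert res.ss_interaction == pytest.approx(ss_i, rel=1e-9,
                                                           abs=1e-12)
            assert res.ss_within_error == pytest.approx(ss_e, rel=1e-9)

    def test_interaction_equals_anova_on_change_scores(self):
        """f_interaction equals the unweighted-means one-way ANOVA F on
        difference scores."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            sizes = rng.integers(3, 9, size=3)
            labels = np.repeat(np.arange(3), sizes)
            n = labels.size
            base = rng.normal(200, 25, size=n)
            follow = base + rng.normal(-8, 6, size=n) + 2.5 * labels
            res = rm_anova_two_timepoints(base, follow, labels)
            d = follow - base
            means = np.array([d[labels == j].mean() for j in range(3)])
            n_h = 3 / (1.0 / sizes).sum()
            ss_b = n_h * ((means - means.mean()) ** 2).sum()
            ss_w = sum(((d[labels == j] - means[j]) ** 2).sum()
                       for j in range(3))
            f = (ss_b / 2) / (ss_w / (n - 3))
            assert res.f_interaction == pytest.approx(f, rel=1e-9)

    def test_balanced_design_matches_pingouin(self):
        """Independent library cross-check on a balanced mixed design."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(99)
        n_per, g = 8, 2
        labels = np.repeat(["a", "b"], n_per)
        base = rng.normal(210, 20, size=n_per * g)
        follow = base + rng.normal(-11, 7, size=n_per * g) + \
            np.where(labels == "b", -5.0, 0.0)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(n_per * g), 2),
            "group": np.tile(labels, 2),
            "time": np.repeat(["pre", "post"], n_per * g),
            "y": np.concatenate([base, follow]),
        })
        aov = pg.mixed_anova(data=df, dv="y", within="time",
                             subject="subject", between="group")
        res = rm_anova_two_timepoints(base, follow, labels)
        f_time = float(aov.loc[aov.Source == "time", "F"].iloc[0])
        f_inter = float(aov.loc[aov.Source == "Interaction", "F"].iloc[0])
        assert res.f_time == pytest.approx(f_time, rel=1e-8)
        assert res.f_interaction == pytest.approx(f_inter, rel=1e-8)

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=60)
    def test_eta2_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, size=n)
        labels[:4] = [0, 0, 1, 1]
        base = rng.normal(0, 1, size=n)
        follow = rng.normal(0, 1, size=n)
        res = rm_anova_two_timepoints(base, follow, labels)
        assert 0.0 <= res.eta2_time <= 1.0
        assert 0.0 <= res.eta2_interaction <= 1.0


# ---------------------------------------------------------------------------
# descriptive summaries


class TestSummarize:
    def test_symmetric_mean_sd(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.style == "mean_sd"
        assert s.central == 3.0

    def test_skewed_median_iqr(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(3.0, 1.2, size=500)
        assert sps.skew(x, bias=False) > 1.0  # oracle skewness formula
        s = summarize(x)
        assert s.style == "median_iqr"
        assert s.spread_low <= s.central <= s.spread_high

    def test_constant_vector(self):
        s = summarize([5.0, 5.0, 5.0])
        assert s.style == "mean_sd"
        assert s.sd == 0.0

    def test_permutation_invariant(self):
        x = [9.0, 1.0, 4.0, 4.0, 100.0, 2.0, 3.0]
        a, b = summarize(x), summarize(list(reversed(x)))
        assert a == b

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            summarize([1.0])
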