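import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coprqa.stats import (
    compare_conditions,
    effect_magnitude,
    effect_size_r,
    friedman,
    normality_gate,
    significance_tier,
    wilcoxon_paired,
)


class TestWilcoxonPaired:
    def test_all_positive_differences_max_w(self):
        a = np.zeros(14)
        b = np.arange(1.0, 15.0)
        w, z, p = wilcoxon_paired(a, b)
        assert w == 105.0  # n(n+1)/2
        assert z == pytest.approx(52.5 / np.sqrt(14 * 15 * 29 / 24), rel=1e-12)
        assert z == pytest.approx(3.2958, abs=1e-4)

    def test_one_negative_smallest_rank(self):
        d = np.arange(1.0, 15.0)
        d[0] = -0.5  # smallest magnitude, negative
        w, z, _ = wilcoxon_paired(np.zeros(14), np.zeros(14) + d)
        assert w == 104.0
        assert z == pytest.approx(3.2330, abs=1e-4)

    def test_antisymmetric_differences_z_zero(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        w, z, p = wilcoxon_paired(np.zeros(6), d)
        assert z == 0.0 and p == 1.0

    def test_sign_flip_negates_z(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        _, z1, p1 = wilcoxon_paired(a, b)
        _, z2, p2 = wilcoxon_paired(b, a)
        assert z2 == pytest.approx(-z1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=14)
            b = a + rng.normal(0.4, 1.0, 14)
            _, z, p = wilcoxon_paired(a, b)
            ref = sps.wilcoxon(b, a, correction=False, method="approx")
            assert abs(z) == pytest.approx(abs(ref.zstatistic), rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_zero_differences_missing(self):
        with pytest.warns(UserWarning, match="zero"):
            w, z, p = wilcoxon_paired(np.ones(5), np.ones(5))
        assert np.isnan(z)

    def test_rank_sum_variant_available(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=14), rng.normal(1.0, 1.0, 14)
        _, z, p = wilcoxon_paired(a, b, variant="rank_sum")
        ref = sps.ranksums(a, b)
        assert z == pytest.approx(ref.statistic)


class TestEffectSize:
    def test_headline_large_effect(self):
        assert round(effect_size_r(3.2958, 14), 2) == 0.88
        assert effect_magnitude(0.88) == "large"

    def test_zero_effect(self):
        assert effect_size_r(0.0, 14) == 0.0
        assert effect_magnitude(0.0) == "negligible"

    def test_medium_effect(self):
        r = effect_size_r(1.5, 14)
        assert r == pytest.approx(0.40, abs=5e-3)
        assert effect_magnitude(r) == "medium"


class TestFriedman:
    def test_identical_conditions_no_effect(self):
        chi2, p = friedman(np.tile([[2.0, 2.0, 2.0]], (6, 1)))
        assert chi2 == 0.0 and p == 1.0

    def test_consistent_ranking_hand_oracle(self):
        # ranks always (1,2,3) over n=3 blocks: chi2 = 6
        chi2, p = friedman(np.array([[1.0, 2.0, 3.0]] * 3))
        assert chi2 == pytest.approx(6.0)
        assert p == pytest.approx(sps.chi2.sf(6.0, 2), rel=1e-12)

    def test_missing_cells_excluded_with_warning(self):
        rng = np.random.default_rng(0)
        tbl = rng.normal(size=(8, 3))
        tbl[2, 1] = np.nan
        with pytest.warns(UserWarning, match="missing cells"):
            chi2, _ = friedman(tbl)
        ref, _ = friedman(np.delete(tbl, 2, axis=0))
        assert chi2 == pytest.approx(ref)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        reject = 0
        n_sim = 2000
        for _ in range(n_sim):
            _, p = friedman(rng.normal(size=(14, 3)))
            reject += p < 0.05
        assert 0.03 <= reject / n_sim <= 0.07

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        tbl = rng.uniform(0.5, 3.0, size=(10, 3))
        chi2_a, _ = friedman(tbl)
        chi2_b, _ = friedman(np.log(tbl) * 5 + 1)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)


class TestNormalityGate:
    def test_heavy_tailed_sample_flagged(self):
        # strongly skewed heavy-tailed draws (log-normal, sigma=2), the kind
        # of shape area-like sway metrics show
        rng = np.random.default_rng(0)
        flagged = 0
        for _ in range(300):
            _, normal = normality_gate({"Free": rng.lognormal(0.0, 2.0, 14)})
            flagged += not normal
        assert flagged / 300 >= 0.95

    def test_gaussian_passes_near_nominal_rate(self):
        rng = np.random.default_rng(1)
        passed = sum(
            normality_gate({"Free": rng.normal(size=14)})[1] for _ in range(300)
        )
        assert 0.90 <= passed / 300 <= 0.99

    def test_constant_sample_forces_nonparametric(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, normal = normality_gate({"Free": np.full(14, 1.0)})
        assert not normal


class TestCompareConditions:
    def frame(self, free, rf, rp):
        rows = []
        for i, (f, a, b) in enumerate(zip(free, rf, rp)):
            rows += [(f"P{i}", "Free", f), (f"P{i}", "RF", a), (f"P{i}", "RP", b)]
        return pd.DataFrame(rows, columns=["participant", "condition", "mdist_cm"])

    def test_strong_effect_runs_pairwise_with_tiers(self):
        rng = np.random.default_rng(2)
        free = rng.normal(1.7, 0.1, 14)
        rf = free + 0.7 + rng.normal(0, 0.05, 14)
        rp = free + 0.65 + rng.normal(0, 0.05, 14)
        comp = compare_conditions(self.frame(free, rf, rp), "mdist_cm")
        assert comp.friedman_p < 0.05
        assert len(comp.pairwise) == 3
        fr_rf = next(p for p in comp.pairwise if p.pair == ("Free", "RF"))
        assert fr_rf.tier == "***"
        assert fr_rf.r == pytest.approx(0.88, abs=0.005)
        assert fr_rf.magnitude == "large"

    def test_null_effect_gates_out_pairwise(self):
        rng = np.random.default_rng(3)
        base = rng.normal(2.0, 0.3, 14)
        comp = compare_conditions(
            self.frame(base, base + rng.normal(0, 0.3, 14),
                       base + rng.normal(0, 0.3, 14)),
            "mdist_cm",
        )
        if comp.friedman_p >= 0.05:
            assert comp.pairwise == []

    def test_tiers(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.03) == "*"
        assert significance_tier(0.005) == "**"
        assert significance_tier(0.0005) == "***"
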