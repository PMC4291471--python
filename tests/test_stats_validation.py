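import math

import numpy as np
import pytest
from scipy import stats as sps

from mtdr.preprocess import FilterConfig
from mtdr.stats_validation import (
    benjamini_hochberg,
    condition_comparison,
    fit_pa_regression,
    partial_spearman,
    ribosomal_load_validation,
    spearman,
)
from mtdr.synthetic_data import SimConfig, simulate_orfs, simulate_profiles


def brute_force_spearman(x, y):
    """Oracle: explicit average ranks then the Pearson formula."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([0.5, 1.0, 2.0, 3.0, 10.0])
        assert spearman(x, x**2).rho == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_hand_rankable_five_points(self):
        # no ties: rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d=[1,-1,1,-1,0]
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        result = spearman(x, y)
        assert result.rho == pytest.approx(1 - 6 * 4 / (5 * 24))  # 0.8
        assert result.rho == pytest.approx(brute_force_spearman(x, y))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.normal(size=n)
            assert spearman(x, y).rho == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        ref = sps.spearmanr(x, y)
        result = spearman(x, y)
        assert result.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert result.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_flagged(self):
        result = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not result.defined and math.isnan(result.rho)


class TestPartialSpearman:
    @staticmethod
    def residual_oracle(x, y, z):
        """Independent construction: correlate the OLS residuals of
        rank(x) and rank(y) after regressing each on rank(z)."""
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rz = sps.rankdata(z)
        zd = np.column_stack([np.ones(len(z)), rz])
        res_x = rx - zd @ np.linalg.lstsq(zd, rx, rcond=None)[0]
        res_y = ry - zd @ np.linalg.lstsq(zd, ry, rcond=None)[0]
        return float(res_x @ res_y / math.sqrt((res_x @ res_x) * (res_y @ res_y)))

    def test_hand_six_point_triple(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        z = [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]
        assert partial_spearman(x, y, z).rho == pytest.approx(
            self.residual_oracle(x, y, z), abs=1e-12
        )

    def test_matches_residual_oracle_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x, y, z = rng.normal(size=(3, n))
            assert partial_spearman(x, y, z).rho == pytest.approx(
                self.residual_oracle(x, y, z), abs=1e-12
            )

    def test_independent_control_approximates_plain_spearman(self):
        rng = np.random.default_rng(3)
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        plain = spearman(x, y).rho
        partial = partial_spearman(x, y, z).rho
        assert partial == pytest.approx(plain, abs=0.02)

    def test_control_equal_to_y_flagged(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        result = partial_spearman(x, y, y)
        assert not result.defined


class TestPARegression:
    def test_synthetic_recovery(self):
        rng = np.random.default_rng(4)
        n = 200
        mtdr = rng.uniform(1, 5, n)
        tai = rng.uniform(0.1, 1.0, n)
        cai = rng.uniform(0.1, 1.0, n)
        pa = 2.0 + 3.0 * mtdr + rng.normal(0, 0.5, n)
        result = fit_pa_regression(pa, mtdr, tai, cai)
        lo, hi = result.ci95["w1"]
        assert lo <= 3.0 <= hi and result.contributes["w1"]
        for name in ("w2", "w3"):
            lo, hi = result.ci95[name]
            assert lo <= 0.0 <= hi and not result.contributes[name]

    def test_noise_free_exact(self):
        rng = np.random.default_rng(5)
        n = 50
        mtdr = rng.uniform(1, 5, n)
        tai = rng.uniform(0.1, 1.0, n)
        cai = rng.uniform(0.1, 1.0, n)
        pa = 1.5 + 2.0 * mtdr - 0.7 * tai + 0.3 * cai
        result = fit_pa_regression(pa, mtdr, tai, cai)
        assert result.coefficients["c"] == pytest.approx(1.5, abs=1e-8)
        assert result.coefficients["w1"] == pytest.approx(2.0, abs=1e-8)
        assert result.coefficients["w2"] == pytest.approx(-0.7, abs=1e-8)
        assert result.coefficients["w3"] == pytest.approx(0.3, abs=1e-8)
        assert result.r2 == pytest.approx(1.0)

    def test_matches_closed_form_two_predictors(self):
        # collapse to two effective predictors by making cai constant-free:
        # check against the normal-equations solution computed directly
        rng = np.random.default_rng(6)
        n = 80
        mtdr = rng.uniform(1, 5, n)
        tai = rng.uniform(0.1, 1.0, n)
        cai = rng.uniform(0.1, 1.0, n)
        pa = rng.normal(size=n)
        design = np.column_stack([np.ones(n), mtdr, tai, cai])
        beta = np.linalg.solve(design.T @ design, design.T @ pa)
        result = fit_pa_regression(pa, mtdr, tai, cai)
        np.testing.assert_allclose(
            [result.coefficients[k] for k in ("c", "w1", "w2", "w3")], beta, atol=1e-10
        )

    def test_duplicated_predictor_raises(self):
        rng = np.random.default_rng(7)
        n = 30
        mtdr = rng.uniform(1, 5, n)
        pa = rng.normal(size=n)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_pa_regression(pa, mtdr, mtdr, mtdr)

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError, match="complete cases"):
            fit_pa_regression([1.0] * 5, [1.0] * 5, [1.0] * 5, [1.0] * 5)


@pytest.fixture(scope="module")
def sim_data():
    cfg = SimConfig(seed=1)
    orfs = simulate_orfs(cfg)
    return orfs, simulate_profiles(orfs, cfg)


class TestRibosomalLoad:
    def test_signal_gives_positive_rho(self, sim_data):
        orfs, profiles = sim_data
        result = ribosomal_load_validation(profiles, orfs, split_seed=7)
        assert result.rho > 0
        one_sided_p = result.p / 2
        assert one_sided_p < 0.01

    def test_shuffle_kills_signal(self, sim_data):
        orfs, profiles = sim_data
        result = ribosomal_load_validation(profiles, orfs, split_seed=7, shuffle_loads=True)
        assert abs(result.rho) < 3.0 / math.sqrt(result.n)

    def test_same_seed_same_split(self, sim_data):
        orfs, profiles = sim_data
        a = ribosomal_load_validation(profiles, orfs, split_seed=11)
        b = ribosomal_load_validation(profiles, orfs, split_seed=11)
        assert a.rho == b.rho and a.n == b.n

    def test_too_few_genes_raises(self):
        from mtdr.io_formats import GeneProfile, ORFRecord

        profiles = [GeneProfile("g1", np.full(50, 5.0))]
        orfs = [ORFRecord("g1", "AAA" * 50)]
        with pytest.raises(ValueError, match="genes passing"):
            ribosomal_load_validation(profiles, orfs, FilterConfig(trim_start=5, trim_end=5))


class TestConditionComparison:
    def _tables(self, rng, n=60, shift=0.0):
        genes = [f"g{i}" for i in range(n)]
        base_mtdr = rng.uniform(1, 4, n)
        base_load = rng.uniform(5, 50, n)
        factor = np.exp(shift * rng.normal(size=n))
        a_scores = dict(zip(genes, base_mtdr * factor))
        b_scores = dict(zip(genes, base_mtdr))
        a_load = dict(zip(genes, base_load * factor**2))
        b_load = dict(zip(genes, base_load))
        return a_scores, b_scores, a_load, b_load

    def test_identical_conditions_degenerate(self):
        rng = np.random.default_rng(8)
        a, b, la, lb = self._tables(rng, shift=0.0)
        result = condition_comparison(a, a, la, la)
        assert result.degenerate
        assert not result.ratio_correlation.defined
        assert result.t_p == pytest.approx(1.0)
        assert result.wilcoxon_p == pytest.approx(1.0)

    def test_condition_shift_detected(self):
        rng = np.random.default_rng(9)
        a, b, la, lb = self._tables(rng, shift=0.5)
        result = condition_comparison(a, b, la, lb)
        assert result.ratio_correlation.rho > 0.5
        assert result.t_p < 0.01 and result.wilcoxon_p < 0.01

    def test_half_quantile_partitions_all_genes(self):
        rng = np.random.default_rng(10)
        a, b, la, lb = self._tables(rng, n=11, shift=0.3)
        result = condition_comparison(a, b, la, lb, q=0.5)
        assert result.n_top + result.n_bottom == result.n

    def test_small_intersection_raises(self):
        rng = np.random.default_rng(11)
        a, b, la, lb = self._tables(rng, n=5)
        with pytest.raises(ValueError, match="shared genes"):
            condition_comparison(a, b, la, lb)


def test_benjamini_hochberg_wrapper():
    pvals = [0.001, 0.01, 0.2, 0.9]
    qvals, reject = benjamini_hochberg(pvals, alpha=0.05)
    assert reject[0] and not reject[3]
    assert np.all(qvals >= pvals)
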