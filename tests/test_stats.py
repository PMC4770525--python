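import math

import numpy as np
import pandas as pd
import pytest

from crtpipe.errors import UndefinedCorrelationError
from crtpipe.stats import (
    binned_density,
    cohort_significance,
    inverse_crt_pairs,
    pearson_fisher,
    percent_per_degree,
)


def exact_r_sample(rho=0.5, n=12, seed=0):
    """Construct (x, y) with sample correlation exactly rho."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x
    e = e / e.std()
    y = rho * x + math.sqrt(1 - rho**2) * e
    return x, y


class TestPearsonFisher:
    def test_perfect_positive_degenerate(self):
        x = np.arange(10.0)
        res = pearson_fisher(x, x)
        assert res.r == 1.0 and res.degenerate and res.ci_low == res.ci_high == 1.0

    def test_perfect_negative_degenerate(self):
        x = np.arange(10.0)
        res = pearson_fisher(x, -x)
        assert res.r == -1.0 and res.degenerate

    def test_hand_computed_ci_n12_r05(self):
        # z' = atanh(0.5) = 0.5493, CI_z = z' +/- 1.96/sqrt(9), mapped by tanh
        x, y = exact_r_sample(rho=0.5, n=12)
        res = pearson_fisher(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        z = math.atanh(0.5)
        assert res.ci_low == pytest.approx(math.tanh(z - 1.96 / 3), abs=1e-3)
        assert res.ci_high == pytest.approx(math.tanh(z + 1.96 / 3), abs=1e-3)
        assert not res.significant  # CI straddles zero at this n

    def test_matches_textbook_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        res = pearson_fisher(x, y)
        ref = pingouin.corr(x, y)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-12)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        lo, hi = ref[ci_col].iloc[0]
        assert res.ci_low == pytest.approx(lo, abs=5e-3)
        assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_r_matches_definition_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            res = pearson_fisher(x, y)
            xm, ym = x - x.mean(), y - y.mean()
            r_def = (xm @ ym) / math.sqrt((xm @ xm) * (ym @ ym))
            assert res.r == pytest.approx(r_def, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_fisher(np.ones(10), np.arange(10.0))

    def test_too_few_pairs_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_fisher([1, 2, 3], [3, 2, 1])

    def test_ci_ordering_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = pearson_fisher(x, y)
            assert -1 <= res.ci_low <= res.r <= res.ci_high <= 1


class TestInverseCrtPairs:
    def make(self, crt, temp, status="used"):
        return pd.DataFrame(
            {
                "status": status,
                "crt_s": crt,
                "spot_temp_c": temp,
            }
        )

    def test_simple_pair(self):
        temp, inv = inverse_crt_pairs(self.make([2.0], [30.0]))
        assert temp[0] == 30.0 and inv[0] == 0.5

    def test_rejected_excluded(self):
        df = pd.concat(
            [self.make([2.0], [30.0]), self.make([1.0], [28.0], status="rejected")]
        )
        temp, inv = inverse_crt_pairs(df)
        assert len(temp) == 1

    def test_all_rejected_gives_empty_then_undefined(self):
        df = self.make([2.0, 1.5], [30.0, 31.0], status="rejected")
        temp, inv = inverse_crt_pairs(df)
        assert len(temp) == 0
        with pytest.raises(UndefinedCorrelationError):
            pearson_fisher(temp, inv)

    def test_nonpositive_crt_dropped(self):
        temp, _ = inverse_crt_pairs(self.make([2.0, 0.0, -1.0], [30.0, 31.0, 32.0]))
        assert len(temp) == 1


class TestBinnedDensity:
    def make(self, crt, temp):
        return pd.DataFrame(
            {"status": "used", "crt_s": crt, "spot_temp_c": temp}
        )

    def test_single_refill_bin_placement(self):
        d = binned_density(self.make([2.05], [28.1]))
        assert d.counts.sum() == 1
        ci = np.flatnonzero(d.counts)[0] // d.counts.shape[1]
        ti = np.flatnonzero(d.counts)[0] % d.counts.shape[1]
        assert d.crt_bin_edges[ci] == pytest.approx(2.0)
        assert d.temp_bin_edges[ti] == pytest.approx(28.0)

    def test_point_on_edge_goes_to_upper_cell(self):
        d = binned_density(self.make([2.0], [28.0]))
        ci = np.flatnonzero(d.counts)[0] // d.counts.shape[1]
        assert d.crt_bin_edges[ci] == pytest.approx(2.0)  # [2.0, 2.1)

    def test_counts_conserved_and_match_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        crt = rng.uniform(0.5, 3.5, 200)
        temp = rng.uniform(25, 35, 200)
        d = binned_density(self.make(crt, temp))
        assert d.counts.sum() == 200
        oracle = np.zeros_like(d.counts)
        for c, t in zip(crt, temp):
            i = np.searchsorted(d.crt_bin_edges, c + 1e-12, side="right") - 1
            j = np.searchsorted(d.temp_bin_edges, t + 1e-12, side="right") - 1
            oracle[i, j] += 1
        np.testing.assert_array_equal(d.counts, oracle)

    def test_fit_line_through_unbinned_points(self):
        temp = np.linspace(25, 33, 50)
        crt = 4.0 - 0.1 * temp
        d = binned_density(self.make(crt, temp))
        assert d.fit_slope == pytest.approx(-0.1, abs=1e-9)
        assert d.fit_intercept == pytest.approx(4.0, abs=1e-7)


class TestCohortAndSlope:
    def make_result(self, sig, w=520):
        from crtpipe.stats import CorrelationResult

        return CorrelationResult(
            r=0.5, n=100, ci_low=0.1 if sig else -0.1, ci_high=0.7,
            significant=sig, wavelength=w,
        )

    def test_11_of_15_is_73_percent(self):
        results = [self.make_result(i < 11) for i in range(15)]
        out = cohort_significance(results)
        assert out[520]["n_significant"] == 11
        assert round(out[520]["pct_significant"]) == 73

    def test_zero_of_15(self):
        out = cohort_significance([self.make_result(False) for _ in range(15)])
        assert out[520]["pct_significant"] == 0.0

    @pytest.mark.parametrize("slope, base, pct", [(-0.14, 2.0, 7.0), (0.0, 2.0, 0.0)])
    def test_percent_per_degree(self, slope, base, pct):
        assert percent_per_degree(slope, base) == pytest.approx(pct)

    def test_percent_per_degree_rejects_bad_baseline(self):
        with pytest.raises(ValueError):
            percent_per_degree(-0.1, 0.0)


class TestSimulationRecovery:
    def test_cooling_gives_significant_positive_r(self, cooling_refills):
        temp, inv = inverse_crt_pairs(cooling_refills)
        res = pearson_fisher(temp, inv)
        assert res.r > 0 and res.significant

    def test_percent_per_degree_recovered(self, cooling_refills):
        # simulated -5%/degC sensitivity, recovered from the binned-density
        # fit slope against the reference CRT
        d = binned_density(cooling_refills)
        pct = percent_per_degree(d.fit_slope, 1.3)
        assert pct == pytest.approx(5.0, abs=1.0)
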