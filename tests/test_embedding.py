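import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srs_chaos.chaotic import logistic_series, lorenz_series
from srs_chaos.embedding import (
    average_mutual_information,
    delay_embed,
    false_nearest_neighbours,
)


class TestDelayEmbed:
    def test_worked_example(self):
        emb = delay_embed([1, 2, 3, 4, 5], m=2, tau=2)
        assert np.array_equal(emb.points, [[1, 3], [2, 4], [3, 5]])

    def test_identity_embedding(self):
        x = np.arange(10.0)
        emb = delay_embed(x, m=1, tau=1)
        assert np.array_equal(emb.points.ravel(), x)

    def test_pipeline_dimensions(self):
        emb = delay_embed(np.sin(np.arange(3200)), m=5, tau=8)
        assert emb.points.shape == (3168, 5)

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 33"):
            delay_embed(np.arange(10.0), m=5, tau=8)

    @given(
        n=st.integers(10, 500),
        m=st.integers(1, 6),
        tau=st.integers(1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_point_count_formula(self, n, m, tau):
        x = np.sin(np.arange(n) * 0.1)
        if n < (m - 1) * tau + 1:
            with pytest.raises(ValueError):
                delay_embed(x, m, tau)
        else:
            emb = delay_embed(x, m, tau)
            assert len(emb.points) == n - (m - 1) * tau
            # coordinate rule: point i, coordinate j = x[i + j*tau]
            i, j = len(emb.points) // 2, m - 1
            assert emb.points[i, j] == x[i + j * tau]


class TestAmi:
    def test_lag_zero_equals_marginal_entropy(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        prof = average_mutual_information(x, max_lag=4, bins=16)
        counts, _ = np.histogram(x, bins=16)
        p = counts / counts.sum()
        h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        assert np.isclose(prof.ami_bits[0], h, atol=1e-10)

    def test_lag_zero_is_maximum_and_nonnegative(self):
        rng = np.random.default_rng(5)
        prof = average_mutual_information(rng.standard_normal(20000), max_lag=16)
        assert prof.ami_bits[0] == prof.ami_bits.max()
        assert (prof.ami_bits >= -1e-12).all()

    def test_reversal_invariance_at_lag_zero(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(3000)
        a = average_mutual_information(x, max_lag=2).ami_bits[0]
        b = average_mutual_information(x[::-1], max_lag=2).ami_bits[0]
        assert np.isclose(a, b, atol=1e-12)

    def test_iid_noise_has_no_lagged_information(self):
        rng = np.random.default_rng(7)
        prof = average_mutual_information(rng.uniform(size=100_000), max_lag=5, bins=16)
        assert prof.ami_bits[1:].max() < 0.1

    def test_sine_first_minimum_near_quarter_period(self):
        # a measured sinusoid (small additive noise keeps the histogram
        # estimator off its degenerate comb artifacts) has its AMI minimum
        # at the quarter period, lag 25 for period 100
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * np.arange(20000) / 100) + 0.05 * rng.standard_normal(20000)
        prof = average_mutual_information(x, max_lag=40, bins=16)
        assert prof.has_local_minimum
        assert 22 <= prof.selected_tau <= 28

    def test_no_local_minimum_falls_back_to_argmin(self, caplog):
        # a monotonically decaying AMI profile: strongly correlated AR(1)
        rng = np.random.default_rng(11)
        x = np.empty(5000)
        x[0] = 0.0
        for i in range(1, len(x)):
            x[i] = 0.999 * x[i - 1] + 0.01 * rng.standard_normal()
        with caplog.at_level("WARNING"):
            prof = average_mutual_information(x, max_lag=5)
        assert not prof.has_local_minimum
        assert prof.selected_tau == int(np.argmin(prof.ami_bits[1:]) + 1)


class TestFnn:
    def test_logistic_map_is_low_dimensional(self):
        x = logistic_series(3000, r=4.0, x0=0.3)
        prof = false_nearest_neighbours(x, tau=1, max_m=5)
        frac_at_2 = prof.fnn_fraction[list(prof.dimensions).index(2)]
        assert frac_at_2 < 0.05

    def test_white_noise_never_converges(self, caplog):
        rng = np.random.default_rng(13)
        with caplog.at_level("WARNING"):
            prof = false_nearest_neighbours(rng.standard_normal(2000), tau=1, max_m=4)
        assert not prof.converged
        assert prof.selected_m == 4

    def test_trivial_threshold_selects_one(self):
        x = logistic_series(1000)
        prof = false_nearest_neighbours(x, tau=1, max_m=3, threshold=1.0)
        assert prof.selected_m == 1

    @pytest.mark.parametrize("series_fn", [
        lambda: logistic_series(3000, r=4.0, x0=0.3),
        lambda: lorenz_series(3000),
    ])
    def test_fraction_non_increasing_for_deterministic_series(self, series_fn):
        prof = false_nearest_neighbours(series_fn(), tau=1, max_m=5)
        diffs = np.diff(prof.fnn_fraction)
        assert (diffs <= 0.02).all()  # allow one small fluctuation

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            false_nearest_neighbours(np.ones(100), tau=1, max_m=3)
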