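"""MK801 cross-talk statistics and spillover arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from papsim.crosstalk import (
    EPSCSeries,
    SpilloverEstimate,
    crosstalk_fraction,
    ecs_increase,
    inv_cv_squared,
    mk801_block_rate,
    paired_pulse_ratio,
    per_discharge_probability,
    subsample_nn_distance,
)
from papsim.errors import InputError
from papsim.synth import gen_epsc_series


def _series_with_reduction(factor: float) -> EPSCSeries:
    """Silent-pathway series whose resumed amplitudes are factor x baseline."""
    import pandas as pd

    base = np.array([100.0, 110.0, 90.0, 105.0, 95.0])
    rows = []
    for k, a in enumerate(base):
        rows.append((k, "silent", "nmdar_baseline", a))
    for k, a in enumerate(base * factor):
        rows.append((10 + k, "silent", "resumed", a))
    return EPSCSeries(
        pd.DataFrame(rows, columns=["trial", "pathway", "phase", "amplitude_pA"])
    )


class TestCrosstalkFraction:
    def test_no_crosstalk(self):
        # resumed amplitudes at baseline level -> 0% cross-activation
        assert crosstalk_fraction(
            _series_with_reduction(1.0)
        ) == pytest.approx(0.0, abs=1e-12)

    def test_forty_percent_reduction(self):
        # resumed mean at 0.60 x baseline -> the post-LTP 40% value
        assert crosstalk_fraction(
            _series_with_reduction(0.60)
        ) == pytest.approx(40.0, abs=1e-9)

    def test_resampling_estimator_mean_unbiased(self):
        # multiplicative noise CV 20%, 10 trials per phase
        vals = [
            crosstalk_fraction(
                gen_epsc_series(
                    crosstalk=0.40, noise_cv=0.2, trials_per_phase=10,
                    seed=seed,
                )[0]
            )
            for seed in range(300)
        ]
        assert np.mean(vals) == pytest.approx(40.0, abs=1.0)

    def test_amplitude_rescaling_invariance(self):
        series, _ = gen_epsc_series(crosstalk=0.3, seed=4)
        scaled = EPSCSeries(
            series.frame.assign(amplitude_pA=series.frame["amplitude_pA"] * 7.3)
        )
        assert crosstalk_fraction(scaled) == pytest.approx(
            crosstalk_fraction(series), rel=1e-12
        )

    def test_too_few_trials_rejected(self):
        series, _ = gen_epsc_series(trials_per_phase=2, seed=0)
        with pytest.raises(InputError):
            crosstalk_fraction(series)


class TestPerDischargeProbability:
    def test_reference_value(self):
        # f = 40% over 120 discharges -> ~0.4% per discharge
        p = per_discharge_probability(0.40, 120)
        assert 100 * p == pytest.approx(0.425, abs=0.005)

    def test_zero_fraction(self):
        assert per_discharge_probability(0.0, 50) == 0.0

    def test_forward_bernoulli_round_trip(self, rng):
        p = per_discharge_probability(0.40, 120)
        n_receptors = 100_000
        blocked = (
            rng.random((120, n_receptors)) < p
        ).any(axis=0)
        f_sim = blocked.mean()
        se = np.sqrt(0.4 * 0.6 / n_receptors)
        assert abs(f_sim - 0.40) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            per_discharge_probability(1.0, 10)
        with pytest.raises(InputError):
            per_discharge_probability(0.2, 0)


class TestSubsampleDistance:
    def test_reference_value(self):
        assert subsample_nn_distance(0.5, 0.02) == pytest.approx(1.84, abs=0.01)

    def test_identity_at_full_density(self):
        assert subsample_nn_distance(0.7, 1.0) == 0.7

    def test_poisson_thinning_oracle(self, rng):
        # thinning a 3D Poisson process by p scales the mean NND by p^(-1/3)
        from scipy.spatial import cKDTree

        box, n = 1000.0, 100_000
        pts = rng.uniform(0, box, (n, 3))
        p = 0.1
        thin = pts[rng.random(n) < p]

        def mean_nnd(arr):
            interior = arr[
                ((arr > 0.15 * box) & (arr < 0.85 * box)).all(axis=1)
            ]
            d, _ = cKDTree(arr).query(interior, k=2)
            return d[:, 1].mean()

        ratio = mean_nnd(thin) / mean_nnd(pts)
        assert ratio == pytest.approx(p ** (-1.0 / 3.0), rel=0.02)

    def test_zero_fraction_rejected(self):
        with pytest.raises(InputError):
            subsample_nn_distance(0.5, 0.0)


class TestEcsIncrease:
    def test_midpoint_estimate_within_expected_window(self):
        # 6.5% astroglial VF, 25% decrease, 17.5% ECS -> ~9.3%, within 5-10%
        val = ecs_increase(0.065, 0.25, 0.175)
        assert val == pytest.approx(0.0929, abs=0.0005)
        assert 0.05 <= val <= 0.10

    def test_zero_decrease(self):
        assert ecs_increase(0.065, 0.0, 0.175) == 0.0

    def test_linearity_in_decrease(self):
        a = ecs_increase(0.065, 0.1, 0.175)
        b = ecs_increase(0.065, 0.2, 0.175)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_ecs_rejected(self):
        with pytest.raises(InputError):
            ecs_increase(0.065, 0.25, 0.0)


class TestPairedPulse:
    @pytest.mark.parametrize(
        "factor,expected", [(1.754, 75.4), (1.0, 0.0), (1.165, 16.5)]
    )
    def test_facilitation_percent(self, factor, expected):
        assert paired_pulse_ratio(10.0, 10.0 * factor) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_first_amplitude_rejected(self):
        with pytest.raises(InputError):
            paired_pulse_ratio(0.0, 5.0)


class TestInvCvSquared:
    def test_binomial_model_prediction(self, rng):
        n_sites, p, q = 20, 0.35, 10.0
        amps = rng.binomial(n_sites, p, 10_000) * q
        expected = n_sites * p / (1 - p)
        assert inv_cv_squared(amps) == pytest.approx(expected, rel=0.05)

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        amps = np.array([8.0, 12.0, 9.0, 15.0, 11.0])
        assert inv_cv_squared(c * amps) == pytest.approx(
            inv_cv_squared(amps), rel=1e-9
        )

    def test_monotone_in_release_probability(self, rng):
        vals = []
        for p in (0.2, 0.4, 0.6):
            amps = rng.binomial(25, p, 20_000) * 10.0
            vals.append(inv_cv_squared(amps))
        assert vals[0] < vals[1] < vals[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            inv_cv_squared(np.full(10, 5.0))


class TestMk801Decay:
    def test_decay_constant_matches_block_probability(self):
        b = 0.2
        k0s = [
            mk801_block_rate(
                gen_epsc_series(
                    mk801_block_prob=b, noise_cv=0.05,
                    trials_per_phase=40, seed=seed,
                )[0]
            ).k0
            for seed in range(20)
        ]
        expected = -1.0 / np.log(1.0 - b)
        assert np.mean(k0s) == pytest.approx(expected, rel=0.10)

    def test_no_block_unidentifiable(self):
        series, _ = gen_epsc_series(
            mk801_block_prob=0.0, noise_cv=0.0, seed=0
        )
        fit = mk801_block_rate(series)
        assert not fit.identifiable
        assert np.isnan(fit.k0)

    def test_equal_release_probability_indistinguishable(self):
        # two pathways simulated with the same parameters give statistically
        # matching decay constants (release probability unchanged by LTP)
        k0_a = [
            mk801_block_rate(
                gen_epsc_series(mk801_block_prob=0.2, noise_cv=0.1,
                                trials_per_phase=40, seed=s)[0]
            ).k0
            for s in range(12)
        ]
        k0_b = [
            mk801_block_rate(
                gen_epsc_series(mk801_block_prob=0.2, noise_cv=0.1,
                                trials_per_phase=40, seed=100 + s)[0]
            ).k0
            for s in range(12)
        ]
        from scipy import stats

        _, pval = stats.ttest_ind(k0_a, k0_b)
        assert pval > 0.05


class TestSpilloverEstimate:
    def test_consistency_contract(self):
        est = SpilloverEstimate(
            cumulative_fraction=0.4,
            discharge_count=120,
            per_discharge_probability=per_discharge_probability(0.4, 120),
        )
        assert est.per_discharge_probability <= est.cumulative_fraction

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InputError):
            SpilloverEstimate(1.2, 10, 0.1)


class TestEpscSeries:
    def test_rectification_on_load(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "trial": range(6),
                "pathway": ["active"] * 6,
                "phase": ["ampar_baseline"] * 6,
                "amplitude_pA": [-50.0, -40.0, 45.0, -55.0, 42.0, -48.0],
            }
        )
        series = EPSCSeries(frame)
        assert (series.frame["amplitude_pA"] > 0).all()

    def test_out_of_order_phases_rejected(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "trial": [0, 1],
                "pathway": ["active", "active"],
                "phase": ["mk801", "ampar_baseline"],
                "amplitude_pA": [10.0, 12.0],
            }
        )
        with pytest.raises(InputError):
            EPSCSeries(frame)
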