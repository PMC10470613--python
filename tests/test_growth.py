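"""Growth quantification: model identities, fit recovery, QC rules, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainpheno import (
    GrowthSimSpec,
    compute_dilution,
    compute_metrics,
    detect_onset,
    fit_gompertz,
    flag_contamination,
    gompertz_model,
    normalize_metrics,
    select_replicates,
    simulate_growth_curve,
)
from strainpheno import synth


class TestGompertzModel:
    def test_asymptote_and_lag_point(self):
        assert gompertz_model(1e6, 0.05, 1.0, 0.3, 2.0) == pytest.approx(1.05)
        assert gompertz_model(2.0, 0.05, 1.0, 0.3, 2.0) == pytest.approx(
            0.05 + np.exp(-np.e)
        )

    def test_zero_A_is_constant_baseline(self):
        t = np.linspace(0, 10, 7)
        np.testing.assert_array_equal(gompertz_model(t, 0.07, 0.0, 0.0, 0.0), 0.07)

    def test_max_slope_equals_mu_max(self):
        """Numerical-derivative oracle: the inflection slope is mu_max."""
        t = np.linspace(0, 30, 300_001)
        y = gompertz_model(t, 0.05, 1.3, 0.47, 3.1)
        slope = np.max(np.diff(y) / np.diff(t))
        assert slope == pytest.approx(0.47, rel=1e-6)


class TestFitGompertz:
    def test_noiseless_recovery_within_a_tenth_percent(self, canonical_spec):
        od = simulate_growth_curve(canonical_spec)
        fit = fit_gompertz(canonical_spec.t_grid, od)
        assert fit.converged and fit.grew
        assert fit.A == pytest.approx(1.0, rel=1e-3)
        assert fit.mu_max == pytest.approx(0.3, rel=1e-3)
        assert fit.lag == pytest.approx(2.0, rel=1e-3)

    def test_constant_series_is_non_grower(self, short_grid):
        fit = fit_gompertz(short_grid, np.full_like(short_grid, 0.05))
        assert not fit.grew
        assert fit.mu_max == 0.0

    def test_noisy_recovery_within_five_percent(self, canonical_spec):
        spec = GrowthSimSpec(y0=0.05, A=1.0, mu_max=0.3, lag=2.0, noise_sd=0.01,
                             t_grid=canonical_spec.t_grid, seed=1)
        fit = fit_gompertz(spec.t_grid, simulate_growth_curve(spec))
        assert fit.mu_max == pytest.approx(0.3, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10 timepoints"):
            fit_gompertz(np.arange(5.0), np.arange(5.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        A=st.floats(0.2, 2.0),
        mu=st.floats(0.05, 1.5),
        lag=st.floats(0.0, 10.0),
    )
    def test_parameter_recovery_property(self, A, mu, lag):
        """Noiseless curves return their generating mu_max within 0.5%."""
        spec = GrowthSimSpec(y0=0.05, A=A, mu_max=mu, lag=lag, noise_sd=0.0,
                             t_grid=synth.default_time_grid(48.0))
        fit = fit_gompertz(spec.t_grid, simulate_growth_curve(spec))
        assert fit.mu_max == pytest.approx(mu, rel=5e-3)


class TestDetectOnset:
    grid = synth.default_time_grid(30.0)

    def test_flat_sterile_curve_has_no_onset(self):
        assert detect_onset(self.grid, np.full_like(self.grid, 0.04)) is None

    def test_step_onset_found_within_one_interval(self):
        od = np.where(self.grid >= 20.0, 0.5, 0.04)
        onset = detect_onset(self.grid, od)
        assert onset == pytest.approx(20.0, abs=synth.SAMPLING_INTERVAL_H + 1e-9)

    def test_curve_already_above_threshold_reports_first_timepoint(self):
        # long baseline window: one early spike barely moves mean and SD
        od = np.full_like(self.grid, 0.04)
        od[0] = 1.0
        onset = detect_onset(self.grid, od, baseline_hours=25.0)
        assert onset == self.grid[0]

    def test_baseline_window_must_be_shorter_than_series(self):
        with pytest.raises(ValueError, match="baseline window"):
            detect_onset(self.grid, np.full_like(self.grid, 0.04),
                         baseline_hours=40.0)


class TestFlagContamination:
    grid = synth.default_time_grid(30.0)

    def _curve(self, onset):
        if onset is None:
            return np.full_like(self.grid, 0.04)
        return np.where(self.grid >= onset, 0.6, 0.04)

    def test_flat_controls_never_discard(self):
        assert not flag_contamination(
            [self._curve(5.0)], [self._curve(None)], self.grid
        )

    @pytest.mark.parametrize(
        "strain_onset,control_onset,expect",
        [
            (25.0, 20.0, True),   # strain after control: discard
            (20.0, 20.0, True),   # same grid point: "at the same time as"
            (5.0, 20.0, False),   # strain clearly earlier: keep
            (None, 20.0, True),   # strain never rises but control does
        ],
    )
    def test_onset_ordering_rule(self, strain_onset, control_onset, expect):
        flagged = flag_contamination(
            [self._curve(strain_onset)], [self._curve(control_onset)], self.grid
        )
        assert flagged is expect

    def test_requires_a_control(self):
        with pytest.raises(ValueError, match="control"):
            flag_contamination([self._curve(5.0)], [], self.grid)


class TestSelectReplicates:
    def test_identical_curves_pick_lexicographic_subset(self):
        curves = [np.ones(20)] * 4
        assert select_replicates(curves) == (0, 1, 2)

    def test_outlier_replicate_excluded(self):
        base = np.linspace(0, 1, 50)
        curves = [base, base + 0.5, base.copy(), base.copy()]
        assert select_replicates(curves) == (0, 2, 3)

    def test_agrees_with_brute_force_and_permutation(self):
        rng = np.random.default_rng(4)
        curves = [rng.normal(size=30) for _ in range(5)]
        chosen = select_replicates(curves, k=3)
        # independent re-enumeration of all triples
        from itertools import combinations

        def total(sub):
            return sum(
                float(np.linalg.norm(curves[i] - curves[j]))
                for i, j in combinations(sub, 2)
            )

        best = min(combinations(range(5), 3), key=total)
        assert chosen == best
        # relabeling permutes the winner accordingly
        perm = [4, 3, 2, 1, 0]
        relabeled = select_replicates([curves[p] for p in perm], k=3)
        assert sorted(perm[i] for i in relabeled) == sorted(chosen)

    def test_too_few_curves_rejected(self):
        with pytest.raises(ValueError):
            select_replicates([np.ones(5), np.ones(5)], k=3)


class TestMetrics:
    def test_identical_noiseless_replicates_recover_closed_form(self, canonical_spec):
        od = simulate_growth_curve(canonical_spec)
        fit = fit_gompertz(canonical_spec.t_grid, od)
        m = compute_metrics([fit] * 3, [od] * 3, "S1", "pH", 6.9, blank=0.05)
        assert m.max_growth_rate == pytest.approx(0.3, rel=1e-3)
        # peak of y0 + A minus the blank (y0) leaves A
        assert m.max_od == pytest.approx(1.0, rel=1e-3)
        assert m.n_replicates_used == 3

    def test_non_growers_yield_zero_metrics(self, short_grid):
        flat = np.full_like(short_grid, 0.05)
        fit = fit_gompertz(short_grid, flat)
        m = compute_metrics([fit] * 3, [flat] * 3, "S1", "pH", 4.0, blank=0.05)
        assert m.max_growth_rate == 0.0
        assert m.max_od == pytest.approx(0.0, abs=1e-9)

    def test_mean_over_replicates(self, short_grid):
        od_a = np.full_like(short_grid, 0.05)
        od_b = np.full_like(short_grid, 0.07)
        fits = [fit_gompertz(short_grid, od) for od in (od_a, od_b)]
        m = compute_metrics(fits, [od_a, od_b], "S1", "pH", 6.9, blank=0.05)
        assert m.max_od == pytest.approx(np.mean([0.0, 0.02]), abs=1e-9)


class TestNormalizeMetrics:
    def _frame(self, rates, ods, strain="S1"):
        return pd.DataFrame(
            {
                "strain": strain,
                "condition_type": "pH",
                "condition_value": np.arange(len(rates), dtype=float),
                "max_growth_rate": rates,
                "max_od": ods,
            }
        )

    def test_division_by_per_strain_maximum(self):
        out = normalize_metrics(self._frame([0.2, 0.4, 0.1, 0.0], [1.0] * 4))
        np.testing.assert_allclose(out["norm_rate"], [0.5, 1.0, 0.25, 0.0])
        np.testing.assert_allclose(out["norm_od"], 1.0)

    def test_single_condition_normalizes_to_one(self):
        out = normalize_metrics(self._frame([0.4], [0.8]))
        assert out["norm_rate"].iloc[0] == 1.0
        assert out["norm_od"].iloc[0] == 1.0

    def test_all_zero_strain_flagged_no_growth(self):
        out = normalize_metrics(self._frame([0.0, 0.0], [0.0, 0.0]))
        assert (out["norm_rate"] == 0).all() and (out["norm_od"] == 0).all()
        assert out["no_growth"].all()

    def test_negative_metric_rejected(self):
        with pytest.raises(ValueError):
            normalize_metrics(self._frame([-0.1], [0.5]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=8))
    def test_output_in_unit_interval_with_max_one(self, rates):
        out = normalize_metrics(self._frame(rates, rates))
        assert ((out["norm_rate"] >= 0) & (out["norm_rate"] <= 1)).all()
        if max(rates) > 0:
            assert out["norm_rate"].max() == pytest.approx(1.0)


class TestDilution:
    def test_plate_loading_scheme(self):
        assert compute_dilution(1, 5, 75) == pytest.approx(16.0)
        assert compute_dilution(5, 5, 75) == pytest.approx(80.0)

    def test_zero_receiving_volume_is_identity(self):
        assert compute_dilution(1, 42.0, 0) == pytest.approx(1.0)

    def test_zero_transfer_volume_rejected(self):
        with pytest.raises(ValueError):
            compute_dilution(1, 0, 75)
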