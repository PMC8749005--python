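"""HRF basis set, GLM design construction, and trial-response estimation."""

import numpy as np
import pandas as pd
import pytest

import neurotraj as nt
from neurotraj.containers import ResponseMatrix, TimeSeriesMatrix
from neurotraj.exceptions import ContractError


class TestHRFBasis:
    def test_canonical_is_zero_at_onset(self, hrf_basis):
        assert hrf_basis.canonical[0] == 0.0

    def test_canonical_peaks_near_five_seconds(self):
        basis = nt.build_hrf_basis(dt=0.01)
        t_peak = basis.t[np.argmax(basis.canonical)]
        assert t_peak == pytest.approx(5.0, abs=0.05)

    def test_canonical_decays_by_32s(self, hrf_basis):
        assert abs(hrf_basis.canonical[-1]) < 1e-3

    def test_delay_derivative_integrates_to_zero(self, hrf_basis):
        # integral of h(t) - h(t-1) over a support where h has decayed
        assert abs(np.sum(hrf_basis.delay_derivative) * hrf_basis.dt) < 1e-3

    def test_basis_functions_linearly_independent(self, hrf_basis):
        B = hrf_basis.as_matrix()
        assert np.linalg.matrix_rank(B) == 3
        assert np.linalg.cond(B) < 1e4


class TestDesignMatrix:
    def _schedule(self, onsets, conditions=None, run_duration=100.0):
        n = len(onsets)
        conditions = conditions or ["1back"] * n
        trials = pd.DataFrame(
            {
                "onset": onsets,
                "duration": 0.5,
                "trial_type": conditions,
                "stimulus_id": 0,
                "is_target": False,
                "accuracy": "unset",
                "run": 0,
                "block": 0,
            }
        )
        return nt.TaskSchedule(trials=trials, run_duration_s=[run_duration])

    def test_single_event_column_equals_sampled_canonical(self, hrf_basis):
        design = nt.build_design_matrix(self._schedule([0.0]), hrf_basis, n_scans=40)
        h_at_scans = hrf_basis.canonical[
            np.round(np.arange(33) / hrf_basis.dt).astype(int)
        ]
        assert np.allclose(design.X[:33, 0], h_at_scans, atol=1e-12)

    def test_shifted_event_gives_shifted_columns(self, hrf_basis):
        d1 = nt.build_design_matrix(self._schedule([2.0]), hrf_basis, n_scans=80)
        d2 = nt.build_design_matrix(self._schedule([42.0]), hrf_basis, n_scans=80)
        assert np.allclose(d1.X[2:40, :3], d2.X[42:80, :3], atol=1e-12)

    def test_overlapping_events_superpose_linearly(self, hrf_basis):
        """Columns of a two-event design equal the sum of single-event
        designs, by linearity of convolution (brute-force check)."""
        d_both = nt.build_design_matrix(self._schedule([5.0, 8.0]), hrf_basis, n_scans=60)
        d_a = nt.build_design_matrix(self._schedule([5.0]), hrf_basis, n_scans=60)
        d_b = nt.build_design_matrix(self._schedule([8.0]), hrf_basis, n_scans=60)
        summed = d_a.X[:, :3] + d_b.X[:, :3]
        combined = d_both.X[:, :3] + d_both.X[:, 3:6]
        assert np.allclose(summed, combined, atol=1e-12)

    def test_event_beyond_scan_end_errors(self, hrf_basis):
        with pytest.raises(ContractError, match="beyond"):
            nt.build_design_matrix(self._schedule([95.0]), hrf_basis, n_scans=50)

    def test_per_run_intercepts_appended(self, hrf_basis, short_config):
        schedule = nt.generate_schedule(short_config)
        n_scans = int(schedule.total_duration_s)
        design = nt.build_design_matrix(schedule, hrf_basis, n_scans=n_scans)
        intercepts = [lab for lab in design.column_labels if lab[0] == "intercept"]
        assert len(intercepts) == short_config.n_runs
        assert design.X.shape[1] == 3 * schedule.n_trials + short_config.n_runs


class TestFitTrialResponses:
    def test_zero_time_series_gives_zero_responses(self, hrf_basis, short_config):
        schedule = nt.label_accuracy(nt.generate_schedule(short_config), 0.85, seed=0)
        n_scans = int(schedule.total_duration_s)
        design = nt.build_design_matrix(schedule, hrf_basis, n_scans=n_scans)
        ts = TimeSeriesMatrix(np.zeros((5, n_scans)))
        responses = nt.fit_trial_responses(ts, design, hrf_basis)
        assert np.allclose(responses.values, 0.0)
        assert responses.samples_per_trial == 9
        assert responses.n_samples == schedule.n_trials * 9

    def test_known_canonical_coefficient_recovered(self, hrf_basis):
        """Forward-simulate y = 2 h(t - onset); the fitted trial response
        equals 2 h on the 9-s window within 1e-8."""
        sched = TestDesignMatrix()._schedule([3.0, 40.0])
        design = nt.build_design_matrix(sched, hrf_basis, n_scans=90)
        y = 2.0 * (design.X[:, 0] + design.X[:, 3])
        ts = TimeSeriesMatrix(y[None, :])
        responses = nt.fit_trial_responses(ts, design, hrf_basis)
        expected = 2.0 * hrf_basis.sample_window(1.0, 9.0)[:, 0]
        for trial in range(2):
            got = responses.values[trial * 9:(trial + 1) * 9, 0]
            assert np.allclose(got, expected, atol=1e-8)

    def test_derivatives_capture_latency_shift(self, hrf_basis):
        """A +1 s shifted response is fit strictly better by the informed
        basis set than by the canonical alone (nested-model residuals)."""
        sched = TestDesignMatrix()._schedule([5.0])
        design = nt.build_design_matrix(sched, hrf_basis, n_scans=60)
        shifted = nt.build_design_matrix(TestDesignMatrix()._schedule([6.0]),
                                         hrf_basis, n_scans=60)
        y = shifted.X[:, 0]
        X_full = design.X
        X_canon = design.X[:, [0, 3]]  # canonical + intercept
        beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
        beta_c, *_ = np.linalg.lstsq(X_canon, y, rcond=None)
        rss_full = np.sum((y - X_full @ beta_f) ** 2)
        rss_canon = np.sum((y - X_canon @ beta_c) ** 2)
        assert rss_full < 0.5 * rss_canon

    def test_fit_is_linear_in_data(self, fitted_responses, noisy_session, hrf_basis):
        sim = noisy_session
        design = nt.build_design_matrix(sim.schedule, hrf_basis, n_scans=sim.ts.n_time)
        scaled = TimeSeriesMatrix(3.0 * sim.ts.data, session=sim.ts.session,
                                  participant=sim.ts.participant)
        responses_scaled = nt.fit_trial_responses(scaled, design, hrf_basis)
        assert np.allclose(responses_scaled.values, 3.0 * fitted_responses.values,
                           rtol=1e-9, atol=1e-9)

    def test_ols_matches_normal_equations_on_small_instance(self, rng):
        """Spot-check the estimator against an explicit (X'X)^-1 X'y solve."""
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 3))
        beta_lstsq, *_ = np.linalg.lstsq(X, Y, rcond=None)
        beta_normal = np.linalg.inv(X.T @ X) @ X.T @ Y
        assert np.allclose(beta_lstsq, beta_normal, atol=1e-10)

    def test_rows_grouped_by_condition_accuracy_in_onset_order(self, fitted_responses):
        labels = fitted_responses.sample_labels
        cells = labels[["condition", "accuracy"]].drop_duplicates().to_numpy().tolist()
        assert cells == sorted(cells)
        for _, grp in labels.groupby(["condition", "accuracy"], sort=False):
            trial_seq = grp["trial"].to_numpy()[::9]
            assert np.all(np.diff(trial_seq) != 0)


class TestConcatenateGroup:
    def _response_stub(self, n_rows, n_regions=4, names=None):
        labels = pd.DataFrame({
            "trial": np.repeat(np.arange(n_rows // 9), 9),
            "condition": "1back", "accuracy": "correct",
            "session": "baseline", "participant": "sub-00",
            "t_index": np.tile(np.arange(9), n_rows // 9),
        })
        return ResponseMatrix(
            values=np.zeros((n_rows, n_regions)), sample_labels=labels,
            region_names=names,
        )

    def test_two_702_row_matrices_concatenate_to_1404(self):
        # 78 trials x 9 samples per condition at TR = 1 s
        merged = nt.concatenate_group(
            [self._response_stub(702), self._response_stub(702)], mode="shared"
        )
        assert merged.n_samples == 1404

    def test_single_input_is_identity(self):
        r = self._response_stub(18)
        merged = nt.concatenate_group([r])
        assert np.array_equal(merged.values, r.values)

    def test_region_mismatch_errors(self):
        a = self._response_stub(18, names=[f"r{i}" for i in range(4)])
        b = self._response_stub(18, names=[f"q{i}" for i in range(4)])
        with pytest.raises(ContractError, match="region"):
            nt.concatenate_group([a, b])
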