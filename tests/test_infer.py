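"""Matching pursuit, filtering, extrapolation, and the inference loop."""

import itertools

import numpy as np
import pytest

import stimsort as ss
from stimsort.hyper import NoiseEstimates, NonstimHyper, StimHyper, StimRangeHyper
from stimsort.infer import (
    SpikeWindow,
    coordinate_ascent,
    extrapolate_artifact,
    filter_artifact,
    make_template_bank,
    matching_pursuit,
    run_amplitude_series,
    run_simplified,
)
from stimsort.kernels import AxisKernelParams, KroneckerKernel

from .conftest import easy_config, random_psd, tiny_config


def true_model(config: ss.SimConfig) -> ss.FittedModel:
    """A FittedModel assembled from the simulator's generating values
    (stimulus-axis envelope projected onto the stationary model class)."""
    n_ranges = len(config.breakpoints) + 1
    return ss.FittedModel(
        nonstim=NonstimHyper(
            rho=config.rho,
            time=config.time_params,
            space=config.space_params,
            stim=AxisKernelParams(lam=config.stim_axis_params.lam),
            phi2=1e-3,
        ),
        stim={
            -1: StimHyper(ranges=[], phi2=1e-3)  # placeholder, replaced below
        },
        noise=NoiseEstimates(sigma2=max(config.sigma_uv**2, 1e-3), phi2=1e-3, phi2_stim=1e-3),
    )


def model_for(ds: ss.SimulatedDataset) -> ss.FittedModel:
    cfg = ds.truth.config
    model = true_model(cfg)
    es = ds.data.stim_electrodes[0]
    n_ranges = len(cfg.breakpoints) + 1
    model.stim = {
        es: StimHyper(
            ranges=[
                StimRangeHyper(
                    rho=cfg.stim_rho[r % len(cfg.stim_rho)],
                    time=cfg.stim_time_params,
                    stim=AxisKernelParams(lam=cfg.stim_lam_s),
                )
                for r in range(n_ranges)
            ],
            phi2=1e-3,
        )
    }
    return model


class TestSpikeWindow:
    def test_default_window_at_20khz(self):
        # 0.25-1.5 ms inclusive -> samples 5..30
        onsets = SpikeWindow().onset_samples(20_000.0, 40)
        np.testing.assert_array_equal(onsets, np.arange(5, 31))

    def test_window_truncated_at_trace_end(self):
        onsets = SpikeWindow().onset_samples(20_000.0, 25)
        assert onsets[-1] == 24

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SpikeWindow(start_ms=2.0, end_ms=3.0).onset_samples(20_000.0, 30)


class TestTemplateBank:
    def _eis(self, peaks, e_count=4, t_prime=8):
        rng = np.random.default_rng(0)
        out = {}
        for n, peak in enumerate(peaks):
            t = rng.normal(size=(e_count, t_prime))
            out[n] = t * (peak / np.abs(t).max())
        return ss.ElectricalImages(out)

    def test_row_count_is_neurons_times_onsets(self):
        bank = make_template_bank(self._eis([50.0]), SpikeWindow(), 20_000.0, 40)
        assert bank.rows.shape[0] == 26  # one neuron, onsets 5..30

    def test_weak_neuron_excluded_at_default_threshold(self):
        bank = make_template_bank(self._eis([50.0, 10.0]), SpikeWindow(), 20_000.0, 40)
        assert bank.neuron_ids == [0]
        assert bank.excluded == [1]

    def test_row_is_shifted_ei(self):
        eis = self._eis([40.0])
        bank = make_template_bank(eis, SpikeWindow(), 20_000.0, 40)
        onset = int(bank.row_onset[3])
        row = bank.rows[3].reshape(4, 40)
        np.testing.assert_array_equal(row[:, onset : onset + 8], eis.templates[0])
        assert np.all(row[:, :onset] == 0)

    def test_truncated_template_norm_uses_in_range_support(self):
        eis = self._eis([40.0], t_prime=20)
        bank = make_template_bank(eis, SpikeWindow(), 20_000.0, 32)
        last = np.nonzero(bank.row_onset == bank.row_onset.max())[0][0]
        onset = int(bank.row_onset[last])
        span = 32 - onset
        expected = np.sum(eis.templates[0][:, :span] ** 2)
        assert bank.norms[last] == pytest.approx(expected, rel=1e-12)

    def test_all_neurons_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            make_template_bank(self._eis([5.0]), SpikeWindow(), 20_000.0, 40)


class TestMatchingPursuit:
    @pytest.fixture(scope="class")
    def bank(self):
        rng = np.random.default_rng(1)
        eis = {}
        for n in range(2):
            t = rng.normal(size=(6, 10))
            eis[n] = t * (80.0 / np.abs(t).max())
        return make_template_bank(ss.ElectricalImages(eis), SpikeWindow(), 20_000.0, 40)

    def test_zero_residual_yields_no_spikes(self, bank):
        spikes, resid = matching_pursuit(np.zeros((6, 40)), bank)
        assert spikes == {}
        np.testing.assert_array_equal(resid, 0.0)

    def test_exact_template_recovered_with_zero_residual(self, bank):
        k = 7
        r = bank.rows[k].reshape(bank.shape)
        spikes, resid = matching_pursuit(r, bank)
        assert spikes == {int(bank.row_neuron[k]): int(bank.row_onset[k])}
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)

    def test_greedy_equals_exhaustive_for_single_neuron(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=(4, 8))
        eis = ss.ElectricalImages({0: t * (60.0 / np.abs(t).max())})
        bank = make_template_bank(eis, SpikeWindow(), 20_000.0, 30)
        for _ in range(50):
            r = rng.normal(0, 40.0, size=(4, 30))
            greedy, _ = matching_pursuit(r, bank)
            # exhaustive: none, or exactly one onset
            best_sse, best = np.sum(r**2), {}
            for k in range(len(bank.rows)):
                sse = np.sum((r.reshape(-1) - bank.rows[k]) ** 2)
                if sse < best_sse:
                    best_sse, best = sse, {0: int(bank.row_onset[k])}
            assert greedy == best

    def test_residual_norm_decreases_with_each_acceptance(self, bank):
        rng = np.random.default_rng(3)
        r = bank.rows[4].reshape(bank.shape) + bank.rows[30].reshape(bank.shape)
        r = r + rng.normal(0, 5.0, size=bank.shape)
        spikes, resid = matching_pursuit(r, bank)
        assert np.sum(resid**2) < np.sum(r**2)
        assert len(spikes) >= 1

    def test_electrode_exclusion_ignores_masked_rows(self, bank):
        r = np.zeros((6, 40))
        r[0] = 1e4  # enormous signal confined to the excluded electrode
        spikes, _ = matching_pursuit(r, bank, exclude_electrodes=(0,))
        assert spikes == {}

    def test_at_most_one_spike_per_neuron(self, bank):
        r = 3.0 * bank.rows[4].reshape(bank.shape)
        spikes, _ = matching_pursuit(r, bank)
        assert len([n for n in spikes if n == int(bank.row_neuron[4])]) <= 1


class TestFilterArtifact:
    def test_zero_noise_returns_input_exactly(self):
        rng = np.random.default_rng(4)
        kern = KroneckerKernel(rho=2.0, factors=[random_psd(rng, 5), random_psd(rng, 3)])
        x = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(filter_artifact(x, kern, 0.0, 10, 0.0), x)

    def test_eigencomponent_shrinks_by_kappa_over_kappa_plus_c(self):
        rng = np.random.default_rng(5)
        a = random_psd(rng, 6)
        w, q = np.linalg.eigh(a)
        kern = KroneckerKernel(rho=1.0, factors=[a])
        top = q[:, -1]
        c = 0.8
        out = filter_artifact(top, kern, sigma2=c, n_j=1, phi2=0.0)
        np.testing.assert_allclose(out, top * (w[-1] / (w[-1] + c)), rtol=1e-10)

    def test_matches_dense_posterior_mean(self):
        rng = np.random.default_rng(6)
        a, b = random_psd(rng, 4), random_psd(rng, 3)
        kern = KroneckerKernel(rho=1.6, factors=[a, b])
        x = rng.normal(size=(4, 3))
        c = 0.9 / 4 + 0.2
        full = 1.6 * np.kron(a, b)
        expected = full @ np.linalg.solve(full + c * np.eye(12), x.reshape(-1))
        out = filter_artifact(x, kern, sigma2=0.9, n_j=4, phi2=0.2)
        np.testing.assert_allclose(out.reshape(-1), expected, rtol=1e-8)


class TestExtrapolateArtifact:
    def test_perfectly_correlated_stimulus_axis_extends_constant(self):
        rng = np.random.default_rng(7)
        kt = random_psd(rng, 4)
        ks = np.ones((5, 5))  # lam -> 0 limit: perfect correlation
        kern = KroneckerKernel(rho=1.0, factors=[kt, ks])
        const = rng.normal(size=(4, 1))
        stack = np.repeat(const, 3, axis=1)
        out = extrapolate_artifact(stack, kern, phi2=0.0)
        np.testing.assert_allclose(out, const[:, 0], rtol=1e-4)

    def test_diagonal_stimulus_axis_predicts_zero(self):
        rng = np.random.default_rng(8)
        kern = KroneckerKernel(rho=1.0, factors=[random_psd(rng, 4), np.eye(5)])
        stack = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            extrapolate_artifact(stack, kern, phi2=0.1), 0.0, atol=1e-12
        )

    def test_matches_dense_conditioning(self):
        rng = np.random.default_rng(9)
        a, b = random_psd(rng, 3), random_psd(rng, 5)
        kern = KroneckerKernel(rho=1.2, factors=[a, b])
        stack = rng.normal(size=(3, 4))
        out = extrapolate_artifact(stack, kern, phi2=0.3)
        full = 1.2 * np.kron(a, b)
        idx = np.arange(15).reshape(3, 5)
        oi, ti = idx[:, :4].reshape(-1), idx[:, 4]
        expected = full[np.ix_(ti, oi)] @ np.linalg.solve(
            full[np.ix_(oi, oi)] + 0.3 * np.eye(12), stack.reshape(-1)
        )
        np.testing.assert_allclose(out, expected, rtol=1e-8)


class TestCoordinateAscent:
    def test_zero_traces_converge_in_one_sweep(self):
        rng = np.random.default_rng(10)
        t = rng.normal(size=(3, 6))
        eis = ss.ElectricalImages({0: t * (50.0 / np.abs(t).max())})
        bank = make_template_bank(eis, SpikeWindow(), 20_000.0, 30)
        a, spikes, sweeps, converged = coordinate_ascent(
            np.zeros((4, 3, 30)), np.zeros((3, 30)), bank, lambda x: x
        )
        assert converged and sweeps == 1
        np.testing.assert_array_equal(a, 0.0)
        assert all(s == {} for s in spikes)

    def test_single_amplitude_recovery_with_known_artifact(self):
        """Planted spikes and a smooth artifact at sigma = 1: spikes must be
        recovered exactly and the artifact to within 3 sigma / sqrt(n)."""
        rng = np.random.default_rng(11)
        e_count, t_count, n_trials = 8, 30, 20
        pos = ss.make_layout(2, 4, 60.0)
        roster = [ss.NeuronSpec(soma_xy=tuple(pos[2]), ei_peak_uv=90.0, mu_a=1.0, s_a=0.2)]
        eis = ss.make_eis(pos, roster, 20_000.0, t_prime=12)
        bank = make_template_bank(eis, SpikeWindow(), 20_000.0, t_count)
        t_ms = np.arange(t_count) / 20.0
        artifact = 30.0 * np.exp(-0.5 * ((t_ms - 0.5) / 0.2) ** 2)[None, :] * np.exp(
            -np.linalg.norm(pos - pos[0], axis=1) / 200.0
        )[:, None]
        true_spikes = [{0: int(rng.integers(5, 18))} for _ in range(n_trials)]
        traces = np.stack(
            [
                artifact
                + bank.waveform(0, sp[0])
                + rng.normal(0, 1.0, size=(e_count, t_count))
                for sp in true_spikes
            ]
        )
        a, spikes, sweeps, converged = coordinate_ascent(
            traces, np.zeros((e_count, t_count)), bank, lambda x: x
        )
        assert converged
        assert spikes == true_spikes
        rmse = np.sqrt(np.mean((a - artifact) ** 2))
        assert rmse < 3.0 * 1.0 / np.sqrt(n_trials)


class TestRunAmplitudeSeries:
    def test_pure_template_matching_when_artifact_free(self):
        """With artifact magnification 0 and no noise the pipeline reduces to
        template matching and recovers every planted spike exactly.

        Neuron thresholds sit well above the lowest amplitude so the
        switching-mean estimate is spike-free, as the centering step assumes.
        """
        pos = ss.make_layout(4, 4, 60.0)
        cfg = tiny_config(
            magnification=0.0,
            sigma_uv=0.0,
            neurons=[
                ss.NeuronSpec(soma_xy=tuple(pos[2]), ei_peak_uv=90.0, mu_a=1.8, s_a=0.25),
                ss.NeuronSpec(soma_xy=tuple(pos[12]), ei_peak_uv=60.0, mu_a=2.4, s_a=0.25),
            ],
        )
        ds = ss.simulate_dataset(cfg, seed=3)
        assert all(len(t) == 0 for t in ds.truth.spikes.spikes[0])
        res = run_simplified(ds.data, ds.eis)
        rep = ss.score(res.spikes, ds.truth.spikes, latency_tol_ms=1e-9)
        assert rep.fp == 0 and rep.fn == 0

    def test_j1_reduces_to_single_batch_coordinate_ascent(self):
        cfg = tiny_config(amplitudes=np.array([2.5, 3.0]), breakpoints=(), n_trials=5)
        ds = ss.simulate_dataset(cfg, seed=4)
        single = ss.AmplitudeSeries(
            traces=[ds.data.traces[0]],
            amplitudes=ds.data.amplitudes[:1],
            sampling_rate_hz=ds.data.sampling_rate_hz,
            stim_electrodes=ds.data.stim_electrodes,
            positions=ds.data.positions,
            breakpoints=[],
        )
        res = run_simplified(single, ds.eis)
        assert res.artifact.artifacts.shape[0] == 1
        assert len(res.spikes.spikes) == 1

    def test_outputs_are_bit_reproducible(self, tiny_dataset, tiny_model):
        a = run_amplitude_series(tiny_dataset.data, tiny_dataset.eis, tiny_model)
        b = run_amplitude_series(tiny_dataset.data, tiny_dataset.eis, tiny_model)
        np.testing.assert_array_equal(a.artifact.artifacts, b.artifact.artifacts)
        assert a.spikes.spikes == b.spikes.spikes

    def test_missing_model_raises_actionable_error(self, tiny_dataset):
        with pytest.raises(ValueError, match="hyperparameters"):
            run_amplitude_series(tiny_dataset.data, tiny_dataset.eis, model=None)

    def test_breakpoint_resets_stim_electrode_initialization(self, tiny_dataset, tiny_model):
        res = run_amplitude_series(tiny_dataset.data, tiny_dataset.eis, tiny_model)
        data = tiny_dataset.data
        es = data.stim_electrodes[0]
        restart = int(np.nonzero(data.amplitudes > data.breakpoints[0])[0][0])
        np.testing.assert_array_equal(res.artifact.initializations[restart][es], 0.0)
        # a non-restart amplitude above j=0 carries a nonzero extrapolation
        other = restart + 1
        assert np.any(res.artifact.initializations[other][es] != 0.0)

    def test_simplified_and_full_agree_in_easy_regime(self):
        """Abundant trials and weak noise: filtering and extrapolation are
        superfluous and both estimators find the same spikes."""
        ds = ss.simulate_dataset(easy_config(), seed=5)
        full = run_amplitude_series(ds.data, ds.eis, model_for(ds))
        simp = run_simplified(ds.data, ds.eis)
        agree = 0
        total = 0
        for bf, bs in zip(full.spikes.spikes, simp.spikes.spikes):
            for tf, tsp in zip(bf, bs):
                total += 1
                agree += tf.keys() == tsp.keys() and all(
                    abs(tf[n] - tsp[n]) <= 1 for n in tf
                )
        assert agree / total >= 0.99


class TestTrialBudget:
    def test_budget_equal_to_trials_matches_full_run(self, tiny_dataset, tiny_model):
        full = run_amplitude_series(tiny_dataset.data, tiny_dataset.eis, tiny_model)
        budgeted = ss.apply_trial_budget(
            tiny_dataset.data, tiny_dataset.eis, tiny_model, budget_n=10**6
        )
        assert budgeted.spikes.spikes == full.spikes.spikes
        np.testing.assert_array_equal(
            budgeted.artifact.artifacts, full.artifact.artifacts
        )

    def test_budgeted_run_agrees_with_full_at_high_snr(self):
        ds = ss.simulate_dataset(easy_config(), seed=6)
        full = run_simplified(ds.data, ds.eis)
        budgeted = run_simplified(ds.data, ds.eis, trial_budget=5)
        agree, total = 0, 0
        for bf, bb in zip(full.spikes.spikes, budgeted.spikes.spikes):
            for tf, tb in zip(bf, bb):
                total += 1
                agree += tf.keys() == tb.keys() and all(abs(tf[n] - tb[n]) <= 1 for n in tf)
        assert agree / total >= 0.99

    def test_budget_of_one_degrades_gracefully(self, tiny_dataset, tiny_model):
        res = ss.apply_trial_budget(
            tiny_dataset.data, tiny_dataset.eis, tiny_model, budget_n=1
        )
        assert res.artifact.artifacts.shape[0] == tiny_dataset.data.J
        assert res.report["trial_budget"] == 1

    def test_nonpositive_budget_rejected(self, tiny_dataset, tiny_model):
        with pytest.raises(ValueError, match=">= 1"):
            ss.apply_trial_budget(tiny_dataset.data, tiny_dataset.eis, tiny_model, budget_n=0)


class TestSpikeAssignmentExport:
    def test_dataframe_columns_and_latency(self, tiny_dataset):
        res = run_simplified(tiny_dataset.data, tiny_dataset.eis)
        df = res.spikes.to_dataframe()
        assert list(df.columns) == [
            "stim_electrode", "amplitude_index", "amplitude_uA",
            "trial", "neuron_id", "onset_sample", "latency_ms",
        ]
        if len(df):
            np.testing.assert_allclose(
                df["latency_ms"], df["onset_sample"] / 20_000.0 * 1e3
            )
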