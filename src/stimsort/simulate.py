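"""Synthetic amplitude-series generator with known ground truth.

Emulates the generative model of the recordings: traces are the linear sum
of a structured stimulation artifact, spike waveforms placed by an
activation model, and white Gaussian noise,

    Y(e, t, j, i) = base(e, t) + A(e, t, j) + sum_n EI_n shifted + eps.

The artifact is drawn from the same structured GP family the inference
assumes (in the original experimental setting artifacts were measured in
TTX-silenced preparations; here they are GP-sampled, which preserves the
qualitative structure: a temporal variance bump shortly after stimulus
onset, spatial decay away from the stimulating electrode within a few
hundred um, smooth growth with amplitude, and an independent, much larger
per-range artifact on the stimulating electrode).  Spiking follows a probit
activation curve per neuron, with spike latency variability that shrinks as
the spike probability approaches one.  ``base`` is a fixed switching
transient shared by all trials, removed by the pipeline's switching-mean
subtraction.

The default scenario is a desk-scale version of a large-array experiment:
64 electrodes, 2 ms of recording at 20 kHz, 20 amplitudes from 0.1 to 4 uA
with one hardware breakpoint, 20 trials per amplitude, 4 neurons, 6 uV
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .data import AmplitudeSeries, ElectricalImages
from .hyper import subtract_switching_mean
from .infer import SpikeAssignment, SpikeWindow, make_template_bank, matching_pursuit
from .kernels import (
    AxisGrid,
    AxisKernelParams,
    KroneckerKernel,
    build_axis_kernel,
    split_by_breakpoints,
)
from .kron import FactoredOperator, kron_sample

__all__ = [
    "NeuronSpec",
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "SimulatedScan",
    "simulate_scan",
    "make_layout",
    "make_eis",
    "sample_artifact",
    "sample_spikes",
    "assemble_traces",
    "simulate_dataset",
    "perturb",
    "baseline_mean_of_traces",
    "run_baseline",
    "score",
    "ScoreReport",
]


def make_layout(rows: int, cols: int, pitch: float = 60.0) -> np.ndarray:
    """Hexagonal-offset electrode grid; positions in um, (rows*cols, 2).

    Odd rows are shifted by half a pitch; row spacing is ``pitch *
    sqrt(3)/2`` so nearest-neighbor distance equals the pitch.
    """
    if rows * cols < 2:
        raise ValueError("layout needs at least 2 electrodes")
    xs, ys = [], []
    for r in range(rows):
        for c in range(cols):
            xs.append(c * pitch + (pitch / 2 if r % 2 else 0.0))
            ys.append(r * pitch * np.sqrt(3) / 2)
    return np.column_stack([xs, ys]).astype(float)


@dataclass(frozen=True)
class NeuronSpec:
    """One simulated neuron: soma position, EI strength, activation model."""

    soma_xy: tuple[float, float]
    ei_peak_uv: float
    mu_a: float   # activation-curve mean, uA
    s_a: float    # activation-curve spread, uA


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Kernel hyperparameters default to values qualitatively matching measured
    artifacts: temporal variance peaking near 0.5 ms, spatial envelope
    negligible beyond ~700 um from the stimulating electrode, smooth growth
    with amplitude.  Latency-model endpoints (high->low spike probability)
    are approximate field-realistic values chosen inside the spike window.
    """

    rows: int = 8
    cols: int = 8
    pitch_um: float = 60.0
    sampling_rate_hz: float = 20_000.0
    n_samples: int = 40                      # 2 ms
    amplitudes: np.ndarray = field(
        default_factory=lambda: np.linspace(0.1, 4.0, 20)
    )
    breakpoints: tuple[float, ...] = (1.5,)
    n_trials: int = 20
    stim_electrode: int | None = None        # default: array center
    sigma_uv: float = 6.0
    neurons: list[NeuronSpec] | None = None  # default roster built per layout
    magnification: float = 1.0               # scales the whole artifact stack

    # non-stimulating-electrode truth kernel; the stimulus-axis envelope
    # gives a gentle (~4x in sd) growth of artifact magnitude across the
    # stimulated range, matching the few-fold growth seen in measured
    # artifacts
    rho: float = 8.0e5
    time_params: AxisKernelParams = field(
        default_factory=lambda: AxisKernelParams(lam=5.0, alpha=2.0, beta=4.0)
    )
    space_params: AxisKernelParams = field(
        default_factory=lambda: AxisKernelParams(lam=0.01, alpha=0.0, beta=0.005)
    )
    stim_axis_params: AxisKernelParams = field(
        default_factory=lambda: AxisKernelParams(lam=0.5, alpha=0.5, beta=0.1)
    )
    # stimulating-electrode truth kernel, per breakpoint range
    stim_rho: tuple[float, ...] = (2.5e6, 5.0e6)
    stim_time_params: AxisKernelParams = field(
        default_factory=lambda: AxisKernelParams(lam=3.0, alpha=1.0, beta=2.0)
    )
    stim_lam_s: float = 0.5

    # latency model: mean and sd endpoints as spike probability goes 0 -> 1
    latency_ms_hi: float = 1.0
    latency_ms_lo: float = 0.4
    latency_sd_hi: float = 0.25
    latency_sd_lo: float = 0.03

    window: SpikeWindow = field(default_factory=SpikeWindow)

    def layout(self) -> np.ndarray:
        return make_layout(self.rows, self.cols, self.pitch_um)

    def resolved_stim_electrode(self, positions: np.ndarray) -> int:
        if self.stim_electrode is not None:
            return self.stim_electrode
        return int(np.argmin(np.linalg.norm(positions - positions.mean(0), axis=1)))

    def resolved_neurons(self, positions: np.ndarray) -> list[NeuronSpec]:
        if self.neurons is not None:
            return self.neurons
        es = self.resolved_stim_electrode(positions)
        p0 = positions[es]
        offsets = [(60.0, 0.0), (-60.0, 52.0), (0.0, -104.0), (120.0, 104.0)]
        peaks = [120.0, 90.0, 70.0, 60.0]
        mus = [1.0, 1.8, 2.6, 3.2]
        return [
            NeuronSpec(
                soma_xy=(p0[0] + dx, p0[1] + dy), ei_peak_uv=pk, mu_a=mu, s_a=0.3
            )
            for (dx, dy), pk, mu in zip(offsets, peaks, mus)
        ]


@dataclass
class GroundTruth:
    """Everything needed to score an inference run against the simulation."""

    artifact: np.ndarray          # (J, E, T), as added to the traces
    base: np.ndarray              # (E, T) switching transient
    spikes: SpikeAssignment
    activation: dict[int, tuple[float, float]]   # neuron -> (mu_a, s_a)
    config: SimConfig

    def centered_artifact(self) -> np.ndarray:
        """Artifact relative to the lowest amplitude — what the pipeline
        estimates after switching-mean subtraction."""
        return self.artifact - self.artifact[0][None]


@dataclass
class SimulatedDataset:
    data: AmplitudeSeries
    eis: ElectricalImages
    truth: GroundTruth


@dataclass
class SimulatedScan:
    """A primary series plus auxiliary series at other stimulating electrodes.

    The auxiliary series exist for hyperparameter estimation: the pooled
    proxy translates each series so its stimulating electrode sits at the
    array center and averages, which cancels electrode-specific spikes while
    reinforcing the artifact.  ``fit_series`` lists the primary series first.
    """

    primary: SimulatedDataset
    fit_series: list[AmplitudeSeries]


def make_eis(
    positions: np.ndarray,
    roster: list[NeuronSpec],
    sampling_rate_hz: float,
    t_prime: int = 21,
    decay_um: float = 70.0,
) -> ElectricalImages:
    """Biphasic, spatially decaying spike templates.

    The waveform is a negative trough followed by a smaller positive
    rebound; amplitude falls off exponentially with distance from the soma
    and is scaled so the peak absolute value equals the roster's EI peak.
    """
    if not roster:
        raise ValueError("neuron roster is empty")
    t_ms = np.arange(t_prime) / sampling_rate_hz * 1e3
    wave = -np.exp(-0.5 * ((t_ms - 0.25) / 0.10) ** 2) + 0.35 * np.exp(
        -0.5 * ((t_ms - 0.55) / 0.18) ** 2
    )
    templates = {}
    for n, spec in enumerate(roster):
        d = np.linalg.norm(positions - np.asarray(spec.soma_xy), axis=1)
        spatial = np.exp(-d / decay_um)
        ei = spatial[:, None] * wave[None, :]
        templates[n] = ei * (spec.ei_peak_uv / np.max(np.abs(ei)))
    return ElectricalImages(templates)


def sample_artifact(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the artifact stack: (J, E, T) total and the (J, T) stimulating-
    electrode part separately.

    Non-stimulating electrodes share one structured GP draw; the stimulating
    electrode is drawn independently per breakpoint range (no correlation
    across ranges).  The whole stack is scaled by ``config.magnification``.
    """
    positions = config.layout()
    es = config.resolved_stim_electrode(positions)
    e_count = len(positions)
    t_ms = np.arange(config.n_samples) / config.sampling_rate_hz * 1e3
    amps = np.asarray(config.amplitudes, dtype=float)
    ns_idx = np.array([e for e in range(e_count) if e != es])
    dist = np.linalg.norm(positions - positions[es], axis=1)

    t_grid = AxisGrid(t_ms)
    e_grid = AxisGrid(positions[ns_idx], dist[ns_idx])
    s_grid = AxisGrid(amps)
    kern = KroneckerKernel(
        rho=config.rho,
        factors=[
            build_axis_kernel(t_grid, config.time_params),
            build_axis_kernel(e_grid, config.space_params),
            build_axis_kernel(s_grid, config.stim_axis_params),
        ],
    )
    draw = kron_sample(FactoredOperator.from_kernel(kern), rng)  # (T, E-1, J)

    stack = np.zeros((len(amps), e_count, config.n_samples))
    stack[:, ns_idx, :] = draw.transpose(2, 1, 0)

    stim_part = np.zeros((len(amps), config.n_samples))
    groups = split_by_breakpoints(amps, config.breakpoints)
    kt = build_axis_kernel(t_grid, config.stim_time_params)
    for r, idx in enumerate(groups):
        ks = build_axis_kernel(AxisGrid(amps[idx]), AxisKernelParams(lam=config.stim_lam_s))
        rho_r = config.stim_rho[r % len(config.stim_rho)]
        block = FactoredOperator(rho=rho_r, factors=[kt, ks])
        stim_part[idx] = kron_sample(block, rng).T  # (len(idx), T)
    stack[:, es, :] = stim_part

    stack *= config.magnification
    return stack, stim_part * config.magnification


def sample_spikes(
    config: SimConfig,
    roster: list[NeuronSpec],
    rng: np.random.Generator,
    n_trials: np.ndarray | None = None,
) -> SpikeAssignment:
    """Draw ground-truth spikes from the probit activation model.

    At amplitude ``a`` neuron n spikes with probability ``Phi((a - mu_a) /
    s_a)``, at most once per trial; the latency is normal with mean and sd
    interpolated between the low- and high-probability endpoints (latency
    jitter shrinks as activation becomes reliable), rounded to the sample
    grid and truncated to the spike window.
    """
    amps = np.asarray(config.amplitudes, dtype=float)
    onsets = config.window.onset_samples(config.sampling_rate_hz, config.n_samples)
    lo_s, hi_s = int(onsets[0]), int(onsets[-1])
    if n_trials is None:
        n_trials = np.full(len(amps), config.n_trials)
    spikes: list[list[dict[int, int]]] = []
    for j, a in enumerate(amps):
        batch: list[dict[int, int]] = [{} for _ in range(int(n_trials[j]))]
        for n, spec in enumerate(roster):
            p = float(norm.cdf((a - spec.mu_a) / spec.s_a))
            mean_ms = config.latency_ms_hi + (config.latency_ms_lo - config.latency_ms_hi) * p
            sd_ms = config.latency_sd_hi + (config.latency_sd_lo - config.latency_sd_hi) * p
            fired = rng.random(int(n_trials[j])) < p
            lat = rng.normal(mean_ms, sd_ms, size=int(n_trials[j]))
            samp = np.clip(
                np.round(lat * config.sampling_rate_hz / 1e3).astype(int), lo_s, hi_s
            )
            for i in np.nonzero(fired)[0]:
                batch[int(i)][n] = int(samp[i])
        spikes.append(batch)
    return SpikeAssignment(
        spikes=spikes, amplitudes=amps, sampling_rate_hz=config.sampling_rate_hz
    )


def _switching_base(config: SimConfig, positions: np.ndarray, es: int) -> np.ndarray:
    """Deterministic switching transient shared by every trial."""
    t_ms = np.arange(config.n_samples) / config.sampling_rate_hz * 1e3
    dist = np.linalg.norm(positions - positions[es], axis=1)
    return 25.0 * np.exp(-dist / 300.0)[:, None] * np.exp(-t_ms / 0.3)[None, :]


def assemble_traces(
    artifact: np.ndarray,
    spikes: SpikeAssignment,
    eis: ElectricalImages,
    sigma: float,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Sum artifact, spike waveforms, and white noise into per-amplitude
    trial blocks (n_j, E, T)."""
    j_count, e_count, t_count = artifact.shape
    out = []
    for j in range(j_count):
        batch = spikes.spikes[j]
        yj = np.zeros((len(batch), e_count, t_count))
        for i, trial in enumerate(batch):
            y = artifact[j].copy()
            if base is not None:
                y = y + base
            for n, t0 in trial.items():
                ei = eis.templates[n]
                span = min(ei.shape[1], t_count - t0)
                y[:, t0 : t0 + span] += ei[:, :span]
            yj[i] = y
        if sigma > 0:
            yj += rng.normal(0.0, sigma, size=yj.shape)
        out.append(yj)
    return out


def simulate_dataset(config: SimConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate a full synthetic amplitude series with ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    positions = config.layout()
    es = config.resolved_stim_electrode(positions)
    roster = config.resolved_neurons(positions)
    eis = make_eis(positions, roster, config.sampling_rate_hz)
    artifact, _ = sample_artifact(config, rng)
    spikes = sample_spikes(config, roster, rng)
    base = _switching_base(config, positions, es)
    traces = assemble_traces(artifact, spikes, eis, config.sigma_uv, rng, base=base)
    data = AmplitudeSeries(
        traces=traces,
        amplitudes=np.asarray(config.amplitudes, dtype=float),
        sampling_rate_hz=config.sampling_rate_hz,
        stim_electrodes=[es],
        positions=positions,
        breakpoints=list(config.breakpoints),
    )
    truth = GroundTruth(
        artifact=artifact,
        base=base,
        spikes=spikes,
        activation={n: (s.mu_a, s.s_a) for n, s in enumerate(roster)},
        config=config,
    )
    return SimulatedDataset(data=data, eis=eis, truth=truth)


def _nonstim_draw(
    config: SimConfig, positions: np.ndarray, es: int, rng: np.random.Generator
) -> np.ndarray:
    """One non-stimulating-electrode artifact draw around stim site ``es``,
    returned as a (J, E, T) stack with the stim electrode's row zero."""
    e_count = len(positions)
    t_ms = np.arange(config.n_samples) / config.sampling_rate_hz * 1e3
    amps = np.asarray(config.amplitudes, dtype=float)
    ns_idx = np.array([e for e in range(e_count) if e != es])
    dist = np.linalg.norm(positions - positions[es], axis=1)
    kern = KroneckerKernel(
        rho=config.rho,
        factors=[
            build_axis_kernel(AxisGrid(t_ms), config.time_params),
            build_axis_kernel(AxisGrid(positions[ns_idx], dist[ns_idx]), config.space_params),
            build_axis_kernel(AxisGrid(amps), config.stim_axis_params),
        ],
    )
    draw = kron_sample(FactoredOperator.from_kernel(kern), rng)  # (T, E-1, J)
    stack = np.zeros((len(amps), e_count, config.n_samples))
    stack[:, ns_idx, :] = draw.transpose(2, 1, 0)
    return stack


def _stim_draw(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Independent per-range stimulating-electrode artifact, (J, T)."""
    amps = np.asarray(config.amplitudes, dtype=float)
    t_ms = np.arange(config.n_samples) / config.sampling_rate_hz * 1e3
    kt = build_axis_kernel(AxisGrid(t_ms), config.stim_time_params)
    out = np.zeros((len(amps), config.n_samples))
    for r, idx in enumerate(split_by_breakpoints(amps, config.breakpoints)):
        ks = build_axis_kernel(AxisGrid(amps[idx]), AxisKernelParams(lam=config.stim_lam_s))
        rho_r = config.stim_rho[r % len(config.stim_rho)]
        out[idx] = kron_sample(FactoredOperator(rho=rho_r, factors=[kt, ks]), rng).T
    return out


def simulate_scan(
    config: SimConfig | None = None, seed: int = 0, n_series: int = 9
) -> SimulatedScan:
    """Generate a stimulation scan: one primary series plus auxiliary series
    at the ``n_series - 1`` other electrodes nearest the array center.

    All series share the same artifact *as a function of position relative
    to the stimulating electrode* (the physical regularity the pooled proxy
    relies on): the auxiliary artifact at electrode e equals the primary
    draw at the electrode with the same relative position, with independent
    draws filling relative positions that fall off the array.  Each series
    gets its own stimulating-electrode artifact (heterogeneous across
    electrodes in real arrays), switching transient, spikes, and noise.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    positions = config.layout()
    es0 = config.resolved_stim_electrode(positions)
    roster = config.resolved_neurons(positions)
    eis = make_eis(positions, roster, config.sampling_rate_hz)

    # primary series (same draw order as simulate_dataset for the first one)
    master, _ = sample_artifact(config, rng)
    spikes0 = sample_spikes(config, roster, rng)
    base0 = _switching_base(config, positions, es0)
    traces0 = assemble_traces(master, spikes0, eis, config.sigma_uv, rng, base=base0)
    primary_data = AmplitudeSeries(
        traces=traces0,
        amplitudes=np.asarray(config.amplitudes, dtype=float),
        sampling_rate_hz=config.sampling_rate_hz,
        stim_electrodes=[es0],
        positions=positions,
        breakpoints=list(config.breakpoints),
    )
    primary = SimulatedDataset(
        data=primary_data,
        eis=eis,
        truth=GroundTruth(
            artifact=master,
            base=base0,
            spikes=spikes0,
            activation={n: (s.mu_a, s.s_a) for n, s in enumerate(roster)},
            config=config,
        ),
    )

    from .hyper import _translation_map

    center_order = np.argsort(np.linalg.norm(positions - positions.mean(0), axis=1))
    aux_electrodes = [int(e) for e in center_order if e != es0][: max(n_series - 1, 0)]

    fit_series = [primary_data]
    for es in aux_electrodes:
        cmap = _translation_map(positions, source=es0, target=es)
        indep = _nonstim_draw(config, positions, es, rng) * config.magnification
        stack = indep.copy()
        ok = (cmap >= 0) & (cmap != es0) & (np.arange(len(positions)) != es)
        stack[:, ok, :] = master[:, cmap[ok], :]
        stack[:, es, :] = _stim_draw(config, rng) * config.magnification
        spikes = sample_spikes(config, roster, rng)
        base = _switching_base(config, positions, es)
        traces = assemble_traces(stack, spikes, eis, config.sigma_uv, rng, base=base)
        fit_series.append(
            AmplitudeSeries(
                traces=traces,
                amplitudes=np.asarray(config.amplitudes, dtype=float),
                sampling_rate_hz=config.sampling_rate_hz,
                stim_electrodes=[es],
                positions=positions,
                breakpoints=list(config.breakpoints),
            )
        )
    return SimulatedScan(primary=primary, fit_series=fit_series)


# ---------------------------------------------------------------------------
# perturbation experiments


def perturb(dataset: SimulatedDataset, mode: str, params: dict, seed: int = 0) -> SimulatedDataset:
    """Return a perturbed copy of a simulated dataset.

    Modes: ``trial_subsample`` (cap trials per amplitude at ``k``),
    ``amplitude_subsample`` (keep every ``step``-th amplitude), and
    ``noise_inject`` (add i.i.d. Gaussian noise of sd ``sigma``).  Ground
    truth is subset consistently so scoring remains valid.
    """
    rng = np.random.default_rng(seed)
    data = dataset.data.copy()
    truth = dataset.truth
    t_spikes = [list(batch) for batch in truth.spikes.spikes]
    artifact = truth.artifact.copy()

    if mode == "trial_subsample":
        k = int(params["k"])
        if k < 1:
            raise ValueError("trial cap must be >= 1")
        data.traces = [y[: min(k, y.shape[0])] for y in data.traces]
        t_spikes = [batch[: min(k, len(batch))] for batch in t_spikes]
    elif mode == "amplitude_subsample":
        step = int(params.get("step", 2))
        keep = np.arange(0, data.J, step)
        data.traces = [data.traces[j] for j in keep]
        data.amplitudes = data.amplitudes[keep]
        t_spikes = [t_spikes[j] for j in keep]
        artifact = artifact[keep]
    elif mode == "noise_inject":
        sigma = float(params["sigma"])
        data.traces = [y + rng.normal(0.0, sigma, size=y.shape) for y in data.traces]
    else:
        raise ValueError(f"unknown perturbation mode '{mode}'")

    new_truth = GroundTruth(
        artifact=artifact,
        base=truth.base,
        spikes=SpikeAssignment(
            spikes=t_spikes,
            amplitudes=data.amplitudes.copy(),
            sampling_rate_hz=data.sampling_rate_hz,
            stim_electrode=truth.spikes.stim_electrode,
        ),
        activation=dict(truth.activation),
        config=truth.config,
    )
    return SimulatedDataset(data=data, eis=dataset.eis, truth=new_truth)


def baseline_mean_of_traces(data: AmplitudeSeries) -> np.ndarray:
    """Reference artifact estimator: the plain mean of raw traces, (J, E, T).

    When spiking is near-deterministic at high amplitudes the mean contains
    the very neural activity being sought, which is the failure mode this
    baseline exhibits.
    """
    return np.stack([y.mean(axis=0) for y in data.traces])


def run_baseline(
    data: AmplitudeSeries, eis: ElectricalImages, config=None
) -> SpikeAssignment:
    """Matching pursuit against the mean-of-traces artifact."""
    from .infer import InferConfig

    config = config or InferConfig()
    centered = subtract_switching_mean(data)
    bank = make_template_bank(
        eis, config.window, data.sampling_rate_hz, data.T, config.ei_threshold_uv
    )
    artifact = baseline_mean_of_traces(centered.data)
    spikes = []
    for j, yj in enumerate(centered.data.traces):
        spikes.append(
            [
                matching_pursuit(yj[i] - artifact[j], bank, (), config.delta_penalty)[0]
                for i in range(yj.shape[0])
            ]
        )
    return SpikeAssignment(
        spikes=spikes,
        amplitudes=data.amplitudes,
        sampling_rate_hz=data.sampling_rate_hz,
        stim_electrode=data.stim_electrodes[0],
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreReport:
    tp: int
    fp: int
    fn: int
    tn: int
    latency_diff_ms: list[float]

    @property
    def fdr(self) -> float:
        return self.fp / (self.fp + self.tp) if (self.fp + self.tp) else 0.0

    @property
    def false_omission_rate(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0

    @property
    def error_rate(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.fp + self.fn) / total if total else 0.0


def score(
    inferred: SpikeAssignment,
    truth: SpikeAssignment,
    latency_tol_ms: float = 0.1,
    neuron_ids: list[int] | None = None,
    amplitude_indices: list[int] | None = None,
) -> ScoreReport:
    """Per-(trial, neuron) confusion counts against ground truth.

    A true positive requires the matching neuron with latency within
    ``latency_tol_ms``; an inferred spike at the wrong latency counts as
    both a miss and a false detection.  FDR = FP/(FP+TP) and the false
    omission rate FN/(FN+TP) follow the series-level error conventions of
    this problem domain.
    """
    if len(inferred.spikes) != len(truth.spikes):
        raise ValueError("inferred and truth cover different numbers of amplitudes")
    if neuron_ids is None:
        neuron_ids = sorted(
            {n for batches in (inferred.spikes, truth.spikes) for b in batches for t in b for n in t}
        )
    tol = latency_tol_ms * truth.sampling_rate_hz / 1e3
    js = range(len(truth.spikes)) if amplitude_indices is None else amplitude_indices
    tp = fp = fn = tn = 0
    diffs = []
    for j in js:
        for i in range(len(truth.spikes[j])):
            inf_trial = inferred.spikes[j][i] if i < len(inferred.spikes[j]) else {}
            tru_trial = truth.spikes[j][i]
            for n in neuron_ids:
                in_inf, in_tru = n in inf_trial, n in tru_trial
                if in_tru and in_inf:
                    d = inf_trial[n] - tru_trial[n]
                    if abs(d) <= tol:
                        tp += 1
                        diffs.append(d / truth.sampling_rate_hz * 1e3)
                    else:
                        fn += 1
                        fp += 1
                elif in_tru:
                    fn += 1
                elif in_inf:
                    fp += 1
                else:
                    tn += 1
    return ScoreReport(tp=tp, fp=fp, fn=fn, tn=tn, latency_diff_ms=diffs)
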