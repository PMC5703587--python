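"""Joint artifact/spike inference by coordinate ascent.

Amplitudes are processed in increasing order.  For each amplitude batch the
algorithm alternates two steps until spike assignments stabilize:

* **matching pursuit** — per trial, greedily add the (neuron, onset) template
  whose subtraction most reduces the squared residual, one spike per neuron
  per trial at most, stopping when no addition helps;
* **artifact filtering** — the GP posterior mean of the artifact given the
  spike-subtracted trial mean, which shrinks each kernel eigencomponent by
  ``kappa / (kappa + sigma2/n_j + phi2)``.

The batch at amplitude j+1 is initialized by the GP conditional mean of the
artifact given the estimates at all lower amplitudes (borrowing strength
from easier, lower-amplitude data).  The stimulating electrode gets its own
per-range kernel; across a hardware breakpoint its artifact is discontinuous,
so its initialization is reset to zero there and the electrode is excluded
from the trial likelihood during the first sweep at the first amplitude after
each breakpoint.

A *simplified* variant replaces filtering by the plain spike-subtracted mean
and extrapolation by copying the previous amplitude's artifact; it needs no
fitted hyperparameters and is accurate when trials are plentiful and noise is
low.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AmplitudeSeries, ElectricalImages, SchemaError
from .hyper import CenteredSeries, FittedModel, subtract_switching_mean
from .kernels import (
    AxisGrid,
    KroneckerKernel,
    StimElectrodeKernel,
    assemble_nonstim_kernel,
    assemble_stim_kernel,
)
from .kron import kron_conditional_mean, posterior_filter

__all__ = [
    "SpikeWindow",
    "TemplateBank",
    "SpikeAssignment",
    "ArtifactEstimate",
    "InferConfig",
    "InferenceResult",
    "make_template_bank",
    "matching_pursuit",
    "filter_artifact",
    "extrapolate_artifact",
    "coordinate_ascent",
    "run_amplitude_series",
    "run_simplified",
    "apply_trial_budget",
]


@dataclass(frozen=True)
class SpikeWindow:
    """Allowed spike-onset interval, in ms after stimulus onset.

    The window is shorter than the refractory period, so each neuron fires at
    most once per trial; onsets live on the discrete sample grid.
    """

    start_ms: float = 0.25
    end_ms: float = 1.5

    def onset_samples(self, sampling_rate_hz: float, n_samples: int) -> np.ndarray:
        lo = int(np.ceil(self.start_ms * sampling_rate_hz / 1e3))
        hi = int(np.floor(self.end_ms * sampling_rate_hz / 1e3))
        hi = min(hi, n_samples - 1)
        if lo > hi or lo < 0:
            raise ValueError(
                f"spike window [{self.start_ms}, {self.end_ms}] ms is empty on a "
                f"{n_samples}-sample grid"
            )
        return np.arange(lo, hi + 1)


#: neurons whose EI never exceeds this peak amplitude are dropped from the
#: bank: below it, accurate spike identification is not guaranteed
DEFAULT_EI_THRESHOLD_UV = 30.0


@dataclass
class TemplateBank:
    """Vectorized spike templates for every retained (neuron, onset) pair.

    Row ``k`` is neuron ``row_neuron[k]``'s EI shifted to onset sample
    ``row_onset[k]`` and truncated at the trace boundary, flattened over
    (electrode, time) in C order.  ``norms`` are squared row norms on the
    truncated support.
    """

    rows: np.ndarray          # (R, E*T)
    norms: np.ndarray         # (R,)
    row_neuron: np.ndarray    # (R,)
    row_onset: np.ndarray     # (R,)
    neuron_ids: list[int]
    excluded: list[int]
    shape: tuple[int, int]    # (E, T)
    _mask_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def waveform(self, neuron: int, onset: int) -> np.ndarray:
        k = np.nonzero((self.row_neuron == neuron) & (self.row_onset == onset))[0]
        if k.size != 1:
            raise KeyError(f"no template for neuron {neuron} at onset {onset}")
        return self.rows[k[0]].reshape(self.shape)

    def masked(self, exclude_electrodes: tuple[int, ...]):
        """(flat column mask, masked squared norms) with electrodes removed."""
        key = tuple(sorted(exclude_electrodes))
        if key not in self._mask_cache:
            e, t = self.shape
            mask = np.ones(e, dtype=bool)
            mask[list(key)] = False
            flat = np.repeat(mask, t)
            self._mask_cache[key] = (flat, (self.rows[:, flat] ** 2).sum(axis=1))
        return self._mask_cache[key]


def make_template_bank(
    eis: ElectricalImages,
    window: SpikeWindow,
    sampling_rate_hz: float,
    n_samples: int,
    strength_threshold: float = DEFAULT_EI_THRESHOLD_UV,
) -> TemplateBank:
    """Build the matching-pursuit bank from EIs.

    Neurons with peak EI amplitude below ``strength_threshold`` (uV) are
    excluded and reported on the bank.
    """
    if strength_threshold < 0:
        raise ValueError("strength threshold must be >= 0")
    onsets = window.onset_samples(sampling_rate_hz, n_samples)
    retained = [n for n in eis.neuron_ids if eis.peak_strength(n) >= strength_threshold]
    excluded = [n for n in eis.neuron_ids if n not in retained]
    if not retained:
        raise ValueError(
            f"no neuron passes the {strength_threshold} uV EI-strength threshold"
        )
    e_count = next(iter(eis.templates.values())).shape[0]
    rows, row_neuron, row_onset = [], [], []
    for n in retained:
        ei = eis.templates[n]
        t_prime = ei.shape[1]
        for t0 in onsets:
            m = np.zeros((e_count, n_samples))
            span = min(t_prime, n_samples - t0)
            m[:, t0 : t0 + span] = ei[:, :span]
            rows.append(m.reshape(-1))
            row_neuron.append(n)
            row_onset.append(int(t0))
    rows = np.array(rows)
    return TemplateBank(
        rows=rows,
        norms=(rows**2).sum(axis=1),
        row_neuron=np.array(row_neuron),
        row_onset=np.array(row_onset),
        neuron_ids=retained,
        excluded=excluded,
        shape=(e_count, n_samples),
    )


def matching_pursuit(
    residual: np.ndarray,
    bank: TemplateBank,
    exclude_electrodes: tuple[int, ...] = (),
    delta_penalty: float = 0.0,
) -> tuple[dict[int, int], np.ndarray]:
    """Greedy template pursuit on one artifact-subtracted trial.

    At each step the squared-error decrease of adding row ``m`` is
    ``delta = 2 <r, m> - ||m||^2``; the maximizer is accepted iff ``delta >
    delta_penalty``, subtracted from the residual, and its neuron retired for
    this trial.  Ties break toward the lower neuron id, then the earlier
    onset (rows are stored in that order, and argmax returns the first
    maximum).  Returns ``{neuron: onset}`` and the final residual.
    """
    r = np.asarray(residual, dtype=float).reshape(-1).copy()
    if exclude_electrodes:
        flat_mask, norms = bank.masked(tuple(exclude_electrodes))
        rows = bank.rows[:, flat_mask]
        r_work = r[flat_mask]
    else:
        rows, norms, r_work = bank.rows, bank.norms, r

    active = np.ones(len(rows), dtype=bool)
    spikes: dict[int, int] = {}
    while active.any():
        delta = np.where(active, 2.0 * (rows @ r_work) - norms, -np.inf)
        k = int(np.argmax(delta))
        if not delta[k] > delta_penalty:
            break
        neuron = int(bank.row_neuron[k])
        spikes[neuron] = int(bank.row_onset[k])
        r_work = r_work - rows[k]
        r -= bank.rows[k]
        active &= bank.row_neuron != neuron
    return spikes, r.reshape(bank.shape)


def filter_artifact(
    mean_spike_subtracted: np.ndarray,
    kernel_j: KroneckerKernel,
    sigma2: float,
    n_j: int,
    phi2: float,
) -> np.ndarray:
    """GP posterior mean of the artifact at one amplitude.

    ``kernel_j`` is the fixed-amplitude sub-kernel (axes time x electrode for
    the non-stimulating block, or time only for the stimulating electrode);
    the input array is shaped like its axes.  With ``sigma2/n_j + phi2 = 0``
    the input is returned unchanged — the filter converges to the plain
    spike-subtracted mean.
    """
    if n_j < 1:
        raise ValueError("n_j must be >= 1")
    return posterior_filter(kernel_j, mean_spike_subtracted, sigma2 / n_j + phi2)


def extrapolate_artifact(
    estimates: np.ndarray,
    kernel: KroneckerKernel,
    phi2: float,
    obs_indices: np.ndarray | None = None,
    target_index: int | None = None,
) -> np.ndarray:
    """Initialize the next amplitude's artifact by GP conditioning.

    ``estimates`` stacks the fitted artifacts for the observed amplitudes
    along the last (stimulus) kernel axis.  The prediction is the noise-free
    posterior mean given those estimates with observation noise ``phi2``.
    """
    estimates = np.asarray(estimates, dtype=float)
    j_obs = estimates.shape[-1]
    if obs_indices is None:
        obs_indices = np.arange(j_obs)
    if target_index is None:
        target_index = j_obs
    out = kron_conditional_mean(
        kernel, np.asarray(obs_indices), np.array([target_index]), estimates, phi2
    )
    return out[..., 0]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class SpikeAssignment:
    """Per (amplitude, trial) spike onsets: ``spikes[j][i] = {neuron: onset}``."""

    spikes: list[list[dict[int, int]]]
    amplitudes: np.ndarray
    sampling_rate_hz: float
    stim_electrode: int = -1

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j, batch in enumerate(self.spikes):
            for i, trial in enumerate(batch):
                for n, t0 in sorted(trial.items()):
                    rows.append(
                        (
                            self.stim_electrode,
                            j,
                            float(self.amplitudes[j]),
                            i,
                            n,
                            t0,
                            t0 / self.sampling_rate_hz * 1e3,
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "stim_electrode",
                "amplitude_index",
                "amplitude_uA",
                "trial",
                "neuron_id",
                "onset_sample",
                "latency_ms",
            ],
        )

    def n_spikes(self) -> int:
        return sum(len(t) for batch in self.spikes for t in batch)


@dataclass
class ArtifactEstimate:
    """Fitted artifacts, their initializations, and convergence diagnostics."""

    artifacts: np.ndarray         # (J, E, T)
    initializations: np.ndarray   # (J, E, T)
    sweeps: list[int]
    residual_norms: list[float]
    warnings: list[str] = field(default_factory=list)


@dataclass
class InferConfig:
    window: SpikeWindow = field(default_factory=SpikeWindow)
    ei_threshold_uv: float = DEFAULT_EI_THRESHOLD_UV
    max_sweeps: int = 5
    delta_penalty: float = 0.0
    latency_stability_samples: int = 1


@dataclass
class InferenceResult:
    artifact: ArtifactEstimate
    spikes: SpikeAssignment
    report: dict


# ---------------------------------------------------------------------------
# coordinate ascent


def _spike_mean(batch_spikes: list[dict[int, int]], bank: TemplateBank) -> np.ndarray:
    """Across-trial mean of the reconstructed spike waveforms."""
    s = np.zeros(bank.shape)
    for trial in batch_spikes:
        for n, t0 in trial.items():
            s += bank.waveform(n, t0)
    return s / max(len(batch_spikes), 1)


def _assignments_stable(
    prev: list[dict[int, int]], new: list[dict[int, int]], latency_tol: int
) -> bool:
    """Sweep-to-sweep stability: identical spike sets per (trial, neuron),
    with onsets allowed to move by at most ``latency_tol`` samples.

    Near-deterministic spiking makes one-sample latency wobble between
    sweeps common (adjacent-onset templates are nearly collinear); such
    changes are treated as "sufficiently small" rather than as
    non-convergence.
    """
    for p, q in zip(prev, new):
        if p.keys() != q.keys():
            return False
        for n, t0 in p.items():
            if abs(q[n] - t0) > latency_tol:
                return False
    return True


def coordinate_ascent(
    traces_j: np.ndarray,
    a0: np.ndarray,
    bank: TemplateBank,
    filter_fn,
    max_sweeps: int = 5,
    exclude_first_sweep: tuple[int, ...] = (),
    delta_penalty: float = 0.0,
    latency_stability_samples: int = 1,
) -> tuple[np.ndarray, list[dict[int, int]], int, bool]:
    """Alternate matching pursuit and artifact filtering on one batch.

    ``filter_fn`` maps a spike-subtracted mean (E, T) to the filtered
    artifact.  Stops when spike-assignment changes between sweeps are
    sufficiently small (see :func:`_assignments_stable`) or the artifact
    update is a fixed point; the artifact is refreshed against the final
    assignments before returning.  Returns (artifact, per-trial spikes,
    sweep count, converged flag).
    """
    a = np.asarray(a0, dtype=float).copy()
    n_j = traces_j.shape[0]
    y_mean = traces_j.mean(axis=0)
    prev: list[dict[int, int]] | None = None
    spikes: list[dict[int, int]] = [{} for _ in range(n_j)]
    converged = False
    sweeps = 0
    for sweep in range(1, max_sweeps + 1):
        sweeps = sweep
        exclude = exclude_first_sweep if sweep == 1 else ()
        spikes = [
            matching_pursuit(traces_j[i] - a, bank, exclude, delta_penalty)[0]
            for i in range(n_j)
        ]
        stable = prev is not None and _assignments_stable(
            prev, spikes, latency_stability_samples
        )
        a_new = filter_fn(y_mean - _spike_mean(spikes, bank))
        fixed_point = np.allclose(a_new, a, rtol=0.0, atol=1e-10)
        a = a_new
        prev = spikes
        if stable or fixed_point:
            converged = True
            break
    return a, spikes, sweeps, converged


# ---------------------------------------------------------------------------
# full series


class _SeriesKernels:
    """Per-series kernel assembly shared by filtering and extrapolation."""

    def __init__(self, data: AmplitudeSeries, model: FittedModel):
        self.stim_electrodes = list(data.stim_electrodes)
        self.nonstim_idx = np.array(
            [e for e in range(data.E) if e not in self.stim_electrodes]
        )
        h = model.nonstim
        t_grid = AxisGrid(data.time_ms)
        dist = data.electrode_distances()
        e_grid = AxisGrid(data.positions[self.nonstim_idx], dist[self.nonstim_idx])
        s_grid = AxisGrid(data.amplitudes)
        self.nonstim = assemble_nonstim_kernel(
            t_grid, e_grid, s_grid, h.time, h.space, h.stim, h.rho, h.phi2
        )
        self.phi2 = h.phi2
        self.sigma2 = model.noise.sigma2
        self.phi2_stim = model.noise.phi2_stim
        self.stim: dict[int, StimElectrodeKernel] = {}
        for e in self.stim_electrodes:
            sh = model.stim[e]
            self.stim[e] = assemble_stim_kernel(
                t_grid,
                data.amplitudes,
                data.breakpoints,
                [{"rho": r.rho, "time": r.time, "stim": r.stim} for r in sh.ranges],
                sh.phi2,
            )

    def nonstim_fixed_j(self, j: int) -> KroneckerKernel:
        return self.nonstim.fixed_axis(axis=2, index=j)

    def stim_fixed_j(self, e: int, j: int) -> KroneckerKernel:
        block = self.stim[e].range_of(j)
        pos = int(np.nonzero(block.j_indices == j)[0][0])
        return KroneckerKernel(
            rho=block.rho * float(block.ks[pos, pos]), factors=[block.kt], jitter=0.0
        )


def _first_after_breakpoints(amplitudes: np.ndarray, breakpoints) -> set[int]:
    out = set()
    for b in breakpoints:
        after = np.nonzero(amplitudes > b)[0]
        if after.size:
            out.add(int(after[0]))
    return out


def _validate(data: AmplitudeSeries, eis: ElectricalImages) -> None:
    eis.validate_against(data)
    if np.any(np.diff(data.amplitudes) <= 0):
        raise SchemaError("amplitudes must be strictly increasing")


def run_amplitude_series(
    data: AmplitudeSeries,
    eis: ElectricalImages,
    model: FittedModel | None,
    config: InferConfig | None = None,
    filtering: str = "kernel",
    extrapolation: str = "kernel",
    trial_budget: int | None = None,
) -> InferenceResult:
    """Run the full inference loop over an amplitude series.

    ``filtering`` is "kernel" (GP posterior mean) or "mean" (plain
    spike-subtracted mean); ``extrapolation`` is "kernel" (GP conditional
    mean over all lower amplitudes) or "naive" (copy the previous artifact).
    The fully simplified combination needs no fitted model.  With
    ``trial_budget`` set, the artifact loop uses only the first
    ``trial_budget`` trials per amplitude and the remaining trials get one
    matching-pursuit pass against the frozen artifact.
    """
    config = config or InferConfig()
    _validate(data, eis)
    needs_model = filtering == "kernel" or extrapolation == "kernel"
    if needs_model and model is None:
        raise ValueError(
            "kernel-based filtering/extrapolation requires fitted hyperparameters; "
            "run hyperparameter estimation first or choose the simplified variant"
        )
    centered = subtract_switching_mean(data)
    bank = make_template_bank(
        eis, config.window, data.sampling_rate_hz, data.T, config.ei_threshold_uv
    )
    kernels = _SeriesKernels(data, model) if needs_model else None
    stim_set = tuple(data.stim_electrodes)
    restart_js = _first_after_breakpoints(data.amplitudes, data.breakpoints)

    e_count, t_count, j_count = data.E, data.T, data.J
    artifacts = np.zeros((j_count, e_count, t_count))
    inits = np.zeros((j_count, e_count, t_count))
    all_spikes: list[list[dict[int, int]]] = []
    sweeps_log, residual_log, warn_log = [], [], []

    if kernels is not None:
        ns_idx = kernels.nonstim_idx
    else:
        ns_idx = np.array([e for e in range(e_count) if e not in stim_set])

    for j in range(j_count):
        yj = centered.data.traces[j]
        n_full = yj.shape[0]
        budget = n_full if trial_budget is None else max(1, min(trial_budget, n_full))
        yj_fit = yj[:budget]

        # --- initialization A0_j
        a0 = np.zeros((e_count, t_count))
        if j > 0:
            if extrapolation == "kernel":
                stack = artifacts[:j][:, ns_idx, :].transpose(2, 1, 0)  # (T, E', j)
                pred = extrapolate_artifact(
                    stack, kernels.nonstim, kernels.phi2,
                    obs_indices=np.arange(j), target_index=j,
                )
                a0[ns_idx] = pred.T
                for e in stim_set:
                    block = kernels.stim[e].range_of(j)
                    obs_in_range = np.array([jj for jj in block.j_indices if jj < j])
                    if obs_in_range.size and j not in restart_js:
                        local = {jj: p for p, jj in enumerate(block.j_indices)}
                        stim_stack = np.stack(
                            [artifacts[jj, e, :] for jj in obs_in_range], axis=-1
                        )
                        a0[e] = extrapolate_artifact(
                            stim_stack,
                            block.as_kron(),
                            kernels.phi2_stim,
                            obs_indices=np.array([local[jj] for jj in obs_in_range]),
                            target_index=local[j],
                        )
            else:
                a0 = artifacts[j - 1].copy()
                if j in restart_js:
                    for e in stim_set:
                        a0[e] = 0.0
        inits[j] = a0

        # --- per-amplitude filter
        if filtering == "kernel":
            kj_ns = kernels.nonstim_fixed_j(j)
            kj_stim = {e: kernels.stim_fixed_j(e, j) for e in stim_set}

            def filt(x, kj_ns=kj_ns, kj_stim=kj_stim, n=budget):
                out = np.zeros_like(x)
                out[ns_idx] = filter_artifact(
                    x[ns_idx].T, kj_ns, kernels.sigma2, n, kernels.phi2
                ).T
                for e, kj in kj_stim.items():
                    out[e] = filter_artifact(
                        x[e], kj, kernels.sigma2, n, kernels.phi2_stim
                    )
                return out

        else:

            def filt(x):
                return x

        exclude = stim_set if j in restart_js else ()
        a_j, spikes_j, sweeps, converged = coordinate_ascent(
            yj_fit,
            a0,
            bank,
            filt,
            max_sweeps=config.max_sweeps,
            exclude_first_sweep=exclude,
            delta_penalty=config.delta_penalty,
            latency_stability_samples=config.latency_stability_samples,
        )
        if not converged:
            warn_log.append(
                f"amplitude {j}: assignments not stabilized after {sweeps} sweeps"
            )
        if budget < n_full:
            for i in range(budget, n_full):
                sp, _ = matching_pursuit(
                    yj[i] - a_j, bank, (), config.delta_penalty
                )
                spikes_j.append(sp)
        artifacts[j] = a_j
        all_spikes.append(spikes_j)
        sweeps_log.append(sweeps)
        resid = sum(
            float(np.sum((yj[i] - a_j - _trial_waveform(spikes_j[i], bank)) ** 2))
            for i in range(n_full)
        )
        residual_log.append(resid)

    assignment = SpikeAssignment(
        spikes=all_spikes,
        amplitudes=data.amplitudes,
        sampling_rate_hz=data.sampling_rate_hz,
        stim_electrode=data.stim_electrodes[0] if data.stim_electrodes else -1,
    )
    artifact = ArtifactEstimate(
        artifacts=artifacts,
        initializations=inits,
        sweeps=sweeps_log,
        residual_norms=residual_log,
        warnings=warn_log,
    )
    report = {
        "filtering": filtering,
        "extrapolation": extrapolation,
        "trial_budget": trial_budget,
        "sweeps": sweeps_log,
        "residual_norms": residual_log,
        "warnings": warn_log,
        "excluded_neurons": bank.excluded,
        "n_spikes": assignment.n_spikes(),
    }
    if warn_log:
        _warnings.warn("; ".join(warn_log), RuntimeWarning, stacklevel=2)
    return InferenceResult(artifact=artifact, spikes=assignment, report=report)


def _trial_waveform(trial_spikes: dict[int, int], bank: TemplateBank) -> np.ndarray:
    s = np.zeros(bank.shape)
    for n, t0 in trial_spikes.items():
        s += bank.waveform(n, t0)
    return s


def run_simplified(
    data: AmplitudeSeries,
    eis: ElectricalImages,
    config: InferConfig | None = None,
    trial_budget: int | None = None,
) -> InferenceResult:
    """Simplified estimator: spike-subtracted mean + naive extrapolation.

    Requires no hyperparameters; accurate when many trials are available and
    noise is low.
    """
    return run_amplitude_series(
        data,
        eis,
        model=None,
        config=config,
        filtering="mean",
        extrapolation="naive",
        trial_budget=trial_budget,
    )


def apply_trial_budget(
    data: AmplitudeSeries,
    eis: ElectricalImages,
    model: FittedModel | None,
    budget_n: int,
    config: InferConfig | None = None,
    **kwargs,
) -> InferenceResult:
    """Artifact estimation on the first ``budget_n`` trials per amplitude;
    remaining trials get matching pursuit against the frozen artifact."""
    if budget_n < 1:
        raise ValueError("trial budget must be >= 1")
    return run_amplitude_series(
        data, eis, model, config=config, trial_budget=budget_n, **kwargs
    )
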