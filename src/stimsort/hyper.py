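"""Hyperparameter estimation for the artifact Gaussian process.

The marginal likelihood of the raw traces is intractable (it sums over all
spiking patterns), so kernel hyperparameters are fitted to a *proxy
artifact*: a cheap, spike-diluted estimate of the true artifact.  For
non-stimulating electrodes the proxy pools trial means across several
stimulating electrodes after translating each recording so its stimulating
electrode sits at the array center — electrode-specific neural activity
averages out while the artifact, which is (approximately) a function of
position relative to the stimulating site, reinforces.  For the stimulating
electrode, where the artifact dwarfs the spikes, the plain trial mean (or
median) suffices.

The noise floors are estimated directly, not by joint likelihood
maximization: ``phi2`` (artifact jitter) from the background window of the
proxy — late time samples at the lowest amplitude on distant electrodes —
and ``sigma2`` (recording noise) from across-trial variability in the same
quiet corner of the data.  Kernel shape parameters are then fitted by
minimizing the Gaussian negative log likelihood of the proxy with ``phi2``
held fixed, using a seeded multistart quasi-Newton optimizer on
log-transformed scale parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import AmplitudeSeries
from .kernels import (
    AxisGrid,
    AxisKernelParams,
    KroneckerKernel,
    assemble_nonstim_kernel,
    split_by_breakpoints,
)
from .kron import FactoredOperator, kron_logdet_shifted, kron_solve_shifted

__all__ = [
    "CenteredSeries",
    "ProxyArtifact",
    "NoiseEstimates",
    "NonstimHyper",
    "StimRangeHyper",
    "StimHyper",
    "FittedModel",
    "subtract_switching_mean",
    "build_proxy_nonstim",
    "build_proxy_stim",
    "estimate_phi2",
    "estimate_sigma2",
    "neg_log_marglik",
    "fit_hyperparameters",
    "fit_stim_hyperparameters",
    "fit_model",
]


@dataclass
class CenteredSeries:
    """Traces after switching-mean subtraction.

    The *switching artifact* is the baseline transient present even at the
    smallest amplitude; its estimate ``switching_mean(e, t)`` is the trial
    mean at the lowest amplitude, subtracted from every trace so the GP can
    assume a zero prior mean.  Adding it back reproduces the raw traces
    exactly.
    """

    data: AmplitudeSeries
    switching_mean: np.ndarray  # (E, T)

    def restore_raw(self) -> AmplitudeSeries:
        raw = self.data.copy()
        raw.traces = [y + self.switching_mean[None] for y in raw.traces]
        return raw


def subtract_switching_mean(raw: AmplitudeSeries) -> CenteredSeries:
    """Estimate the switching artifact and center all traces on it."""
    if raw.traces[0].shape[0] < 1:
        raise ValueError("no trials at the lowest stimulation amplitude")
    mu = raw.traces[0].mean(axis=0)
    centered = raw.copy()
    centered.traces = [y - mu[None] for y in centered.traces]
    return CenteredSeries(data=centered, switching_mean=mu)


@dataclass
class ProxyArtifact:
    """Cheap artifact estimate used as the hyperparameter-fitting target.

    ``values`` is (T, E', J) for the pooled non-stimulating proxy (E' =
    retained electrodes) or (T, J) for a stimulating electrode.  Grids carry
    the covariates the kernels are built on.
    """

    values: np.ndarray
    time_ms: np.ndarray
    amplitudes: np.ndarray
    electrode_indices: np.ndarray | None = None
    positions: np.ndarray | None = None          # positions of retained electrodes
    center_distance: np.ndarray | None = None    # distance to (virtual) stim site
    provenance: dict = field(default_factory=dict)

    def grids(self) -> tuple[AxisGrid, AxisGrid | None, AxisGrid]:
        t_grid = AxisGrid(self.time_ms)
        e_grid = None
        if self.positions is not None:
            e_grid = AxisGrid(self.positions, self.center_distance)
        return t_grid, e_grid, AxisGrid(self.amplitudes)


def _translation_map(positions: np.ndarray, source: int, target: int) -> np.ndarray:
    """Map electrode indices under the translation taking ``source`` to
    ``target``; -1 where the translated position falls off the array.

    For electrode ``e`` in the translated (target-centered) frame, entry
    ``e`` is the index of the electrode recorded at the corresponding
    position relative to the ``source`` stimulating electrode.
    """
    offset = positions[source] - positions[target]
    tol = 0.25 * _min_pitch(positions)
    out = np.full(len(positions), -1, dtype=int)
    for e in range(len(positions)):
        d = np.linalg.norm(positions - (positions[e] + offset), axis=1)
        k = int(np.argmin(d))
        if d[k] <= tol:
            out[e] = k
    return out


def _min_pitch(positions: np.ndarray) -> float:
    diff = positions[:, None, :] - positions[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def center_electrode(positions: np.ndarray) -> int:
    """Index of the electrode nearest the array centroid."""
    return int(np.argmin(np.linalg.norm(positions - positions.mean(0), axis=1)))


def build_proxy_nonstim(
    datasets: list[CenteredSeries],
    n_sample: int = 15,
    keep_frac: float = 0.25,
    seed: int | None = 0,
) -> ProxyArtifact:
    """Pool translated trial means across stimulating electrodes.

    Each dataset's traces are re-indexed as if stimulation had occurred at
    the array center, then averaged across datasets per (electrode, time,
    amplitude).  Electrodes whose translated position falls off the array in
    a given dataset are excluded from that dataset's contribution (counts
    adjusted).  Only the ``keep_frac`` of electrodes closest to the center
    are retained — distant electrodes contribute mostly noise.
    """
    if not datasets:
        raise ValueError("at least one stimulating-electrode dataset is required")
    base = datasets[0].data
    positions = base.positions
    if len(datasets) > n_sample:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(len(datasets), size=n_sample, replace=False))
        datasets = [datasets[i] for i in chosen]
    center = center_electrode(positions)
    E, T, J = base.E, base.T, base.J
    acc = np.zeros((E, T, J))
    count = np.zeros(E)
    used = []
    for ds in datasets:
        es = ds.data.stim_electrodes[0]
        cmap = _translation_map(positions, source=es, target=center)
        trial_mean = np.stack([y.mean(axis=0) for y in ds.data.traces], axis=-1)  # (E,T,J)
        # drop translations that fall off the array or land on a stimulating
        # electrode (whose artifact follows the separate stimulating model)
        ok = (cmap >= 0) & ~np.isin(cmap, ds.data.stim_electrodes)
        acc[ok] += trial_mean[cmap[ok]]
        count[ok] += 1
        used.append(es)
    valid = count > 0
    dist = np.linalg.norm(positions - positions[center], axis=1)
    n_keep = max(2, int(np.ceil(keep_frac * E)))
    order = np.argsort(dist + np.where(valid, 0.0, np.inf))
    keep = np.sort(order[:n_keep])
    values = (acc[keep] / count[keep, None, None]).transpose(1, 0, 2)  # (T, E', J)
    return ProxyArtifact(
        values=values,
        time_ms=base.time_ms,
        amplitudes=base.amplitudes,
        electrode_indices=keep,
        positions=positions[keep],
        center_distance=dist[keep],
        provenance={
            "stim_electrodes": used,
            "center": center,
            "n_excluded": int((~valid).sum()),
            # effective trace count behind each proxy entry: D datasets each
            # contributing a trial mean plus the (independent) switching-mean
            # noise of its lowest amplitude
            "n_averaged": float(
                np.mean(count[keep])
                / (1.0 / np.mean(base.n_trials) + 1.0 / base.n_trials[0])
            ),
        },
    )


def build_proxy_stim(
    centered: CenteredSeries, electrode: int | None = None, statistic: str = "mean"
) -> ProxyArtifact:
    """Trial mean (default) or median at the stimulating electrode, (T, J)."""
    data = centered.data
    e = data.stim_electrodes[0] if electrode is None else electrode
    reducer = {"mean": np.mean, "median": np.median}[statistic]
    values = np.stack([reducer(y[:, e, :], axis=0) for y in data.traces], axis=-1)
    return ProxyArtifact(
        values=values,
        time_ms=data.time_ms,
        amplitudes=data.amplitudes,
        provenance={
            "electrode": e,
            "statistic": statistic,
            "n_averaged": float(
                1.0 / (1.0 / np.mean(data.n_trials) + 1.0 / data.n_trials[0])
            ),
        },
    )


def estimate_phi2(
    proxy: ProxyArtifact,
    time_frac: float = 0.25,
    dist_frac: float = 0.25,
    sigma2: float | None = None,
    n_averaged: float | None = None,
) -> float:
    """Artifact jitter from the proxy's background window.

    The window is the last ``time_frac`` of time samples at the lowest
    amplitude; for the pooled proxy it is further restricted to the farthest
    ``dist_frac`` of retained electrodes.  When the switching-mean centering
    makes the lowest-amplitude proxy vanish identically (it subtracts exactly
    that amplitude's trial mean), the window falls back to the lowest
    amplitude with a non-degenerate proxy.

    The background variance of the proxy contains, besides the true artifact
    jitter, the residual recording noise of the trial averaging,
    ``sigma2 / n_averaged``.  When ``sigma2`` and the number of traces pooled
    per proxy entry are supplied, that contribution is subtracted (floored at
    zero) so it is not double-counted against the per-trial noise term later.
    """
    t0 = int(np.floor((1 - time_frac) * proxy.values.shape[0]))
    if t0 >= proxy.values.shape[0]:
        raise ValueError("background time window is empty")
    if proxy.values.ndim == 3:
        d = proxy.center_distance
        cut = np.quantile(d, 1 - dist_frac)
        far = d >= cut
        windows = [proxy.values[t0:, far, j] for j in range(proxy.values.shape[-1])]
    else:
        windows = [proxy.values[t0:, j] for j in range(proxy.values.shape[-1])]
    if windows[0].size < 2:
        raise ValueError("background window has fewer than 2 entries")
    scale = float(np.max(np.abs(proxy.values)))
    correction = 0.0
    if sigma2 is not None and n_averaged:
        correction = sigma2 / n_averaged
    for background in windows:
        if np.max(np.abs(background)) > 1e-8 * max(scale, 1.0):
            return float(max(np.var(background, ddof=1) - correction, 0.0))
    return 0.0


def estimate_sigma2(centered: CenteredSeries, dist_frac: float = 0.25) -> float:
    """Recording noise from across-trial variance in the quietest data.

    Uses trials at the lowest amplitude on the ``dist_frac`` of electrodes
    farthest from the stimulation site; a common artifact shared by all
    trials cancels in the across-trial variance.
    """
    y = centered.data.traces[0]
    if y.shape[0] < 2:
        raise ValueError("need >= 2 trials at the lowest amplitude to estimate sigma2")
    d = centered.data.electrode_distances()
    far = d >= np.quantile(d, 1 - dist_frac)
    return float(np.mean(np.var(y[:, far, :], axis=0, ddof=1)))


def neg_log_marglik(values: np.ndarray, kernel: KroneckerKernel) -> float:
    """Gaussian NLL of the proxy, ``0.5 v' K^-1 v + 0.5 log|K|``.

    ``K`` includes the kernel's jitter on the diagonal; the ``2*pi``
    normalization constant is excluded (it does not depend on the
    hyperparameters).
    """
    op = FactoredOperator.from_kernel(kernel)
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size != op.total_dim:
        raise ValueError(f"proxy of size {v.size} incompatible with kernel axes {op.sizes}")
    return float(0.5 * v @ kron_solve_shifted(op, v) + 0.5 * kron_logdet_shifted(op))


# ---------------------------------------------------------------------------
# fitted-hyperparameter containers


@dataclass
class NoiseEstimates:
    sigma2: float
    phi2: float
    phi2_stim: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma2, self.phi2, self.phi2_stim) < 0:
            raise ValueError("noise variances must be >= 0")

    def to_dict(self) -> dict:
        return {"sigma2": self.sigma2, "phi2": self.phi2, "phi2_stim": self.phi2_stim}


@dataclass
class NonstimHyper:
    """Fitted kernel of the non-stimulating electrodes."""

    rho: float
    time: AxisKernelParams
    space: AxisKernelParams
    stim: AxisKernelParams
    phi2: float

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "phi2": self.phi2,
            "time": self.time.to_dict(),
            "space": self.space.to_dict(),
            "stim": self.stim.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NonstimHyper":
        return cls(
            rho=d["rho"],
            phi2=d["phi2"],
            time=AxisKernelParams.from_dict(d["time"]),
            space=AxisKernelParams.from_dict(d["space"]),
            stim=AxisKernelParams.from_dict(d["stim"]),
        )


@dataclass
class StimRangeHyper:
    """Fitted stimulating-electrode kernel for one inter-breakpoint range."""

    rho: float
    time: AxisKernelParams
    stim: AxisKernelParams

    def to_dict(self) -> dict:
        return {"rho": self.rho, "time": self.time.to_dict(), "stim": self.stim.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "StimRangeHyper":
        return cls(
            rho=d["rho"],
            time=AxisKernelParams.from_dict(d["time"]),
            stim=AxisKernelParams.from_dict(d["stim"]),
        )


@dataclass
class StimHyper:
    ranges: list[StimRangeHyper]
    phi2: float

    def to_dict(self) -> dict:
        return {"phi2": self.phi2, "ranges": [r.to_dict() for r in self.ranges]}

    @classmethod
    def from_dict(cls, d: dict) -> "StimHyper":
        return cls(ranges=[StimRangeHyper.from_dict(r) for r in d["ranges"]], phi2=d["phi2"])


@dataclass
class FittedModel:
    """Everything inference needs: kernels plus noise floors."""

    nonstim: NonstimHyper
    stim: dict[int, StimHyper]
    noise: NoiseEstimates

    def to_dict(self) -> dict:
        return {
            "nonstim": self.nonstim.to_dict(),
            "stim": {str(k): v.to_dict() for k, v in self.stim.items()},
            "noise": self.noise.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            nonstim=NonstimHyper.from_dict(d["nonstim"]),
            stim={int(k): StimHyper.from_dict(v) for k, v in d["stim"].items()},
            noise=NoiseEstimates(**d["noise"]),
        )


# ---------------------------------------------------------------------------
# optimization

#: default box bounds, per covariate unit: inverse length-scales, envelope
#: shape and rate.  Guard against degenerate flat or spiky kernels on the
#: short grids used here.
LAM_BOUNDS = (1e-3, 1e3)
ALPHA_BOUNDS = (0.0, 20.0)
BETA_BOUNDS = (1e-6, 1e3)
RHO_BOUNDS = (1e-12, 1e12)


@dataclass
class FitReport:
    nll: float
    nll_init: float
    converged: bool
    n_evaluations: int
    message: str = ""


def _pack(rho, t: AxisKernelParams, e: AxisKernelParams | None, lam_s) -> np.ndarray:
    z = [np.log(rho), np.log(t.lam), t.alpha, np.log(max(t.beta, BETA_BOUNDS[0]))]
    if e is not None:
        z += [np.log(e.lam), e.alpha, np.log(max(e.beta, BETA_BOUNDS[0]))]
    z.append(np.log(lam_s))
    return np.array(z)


def _unpack(z: np.ndarray, with_space: bool):
    rho = float(np.exp(z[0]))
    t = AxisKernelParams(lam=float(np.exp(z[1])), alpha=float(z[2]), beta=float(np.exp(z[3])))
    if with_space:
        e = AxisKernelParams(lam=float(np.exp(z[4])), alpha=float(z[5]), beta=float(np.exp(z[6])))
        lam_s = float(np.exp(z[7]))
        return rho, t, e, lam_s
    return rho, t, None, float(np.exp(z[4]))


def _bounds(with_space: bool):
    lo_lam, hi_lam = np.log(LAM_BOUNDS[0]), np.log(LAM_BOUNDS[1])
    lo_b, hi_b = np.log(BETA_BOUNDS[0]), np.log(BETA_BOUNDS[1])
    axis = [(lo_lam, hi_lam), ALPHA_BOUNDS, (lo_b, hi_b)]
    b = [(np.log(RHO_BOUNDS[0]), np.log(RHO_BOUNDS[1]))] + axis
    if with_space:
        b += axis
    b.append((lo_lam, hi_lam))
    return b


def _default_init(proxy: ProxyArtifact, phi2: float, with_space: bool):
    """Heuristic starting point: moderate length-scales, mild envelopes,
    rho matched to the proxy's overall variance."""
    t_span = proxy.time_ms[-1] - proxy.time_ms[0]
    a_span = proxy.amplitudes[-1] - proxy.amplitudes[0] or 1.0
    t0 = AxisKernelParams(lam=4.0 / max(t_span, 1e-6), alpha=1.0, beta=2.0 / max(t_span, 1e-6))
    e0 = None
    if with_space:
        d = proxy.center_distance
        d_span = max(d.max() - d.min(), 1.0)
        e0 = AxisKernelParams(lam=4.0 / d_span, alpha=0.0, beta=1.0 / d_span)
        env_e = np.exp(-d * e0.beta)
    env_t = (proxy.time_ms ** t0.alpha) * np.exp(-proxy.time_ms * t0.beta)
    scale = float(np.mean(env_t**2)) * (float(np.mean(env_e**2)) if with_space else 1.0)
    var = max(float(np.var(proxy.values)) - phi2, 1e-6)
    rho0 = var / max(scale, 1e-12)
    return rho0, t0, e0, 1.0 / a_span


def _multistart_minimize(fun, z0, bounds, seed, n_starts: int):
    """Seeded multistart L-BFGS-B followed by a simplex polish.

    The likelihood surface has long curved ridges (rho trades off against
    the envelope shape), on which quasi-Newton steps with finite-difference
    gradients stall; a Nelder-Mead polish from the best point closes the
    remaining gap reliably.
    """
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.clip(z0, lo, hi)]
    for _ in range(n_starts - 1):
        starts.append(np.clip(z0 + rng.normal(0, 0.7, size=len(z0)), lo, hi))
    best = None
    n_eval = 0
    for s in starts:
        res = optimize.minimize(fun, s, method="L-BFGS-B", bounds=bounds)
        n_eval += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(
        lambda z: fun(np.clip(z, lo, hi)),
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-7, "fatol": 1e-9, "adaptive": True},
    )
    n_eval += polish.nfev
    if polish.fun < best.fun:
        polish.x = np.clip(polish.x, lo, hi)
        best = polish
    return best, n_eval


def fit_hyperparameters(
    proxy: ProxyArtifact,
    phi2: float,
    init: NonstimHyper | None = None,
    seed: int = 0,
    n_starts: int = 5,
) -> tuple[NonstimHyper, FitReport]:
    """Fit the non-stimulating-electrode kernel to the pooled proxy.

    ``phi2`` is held fixed (estimated beforehand from the background
    window); the optimizer works on log-transformed (rho, lambda, beta) and
    bounded alpha, with a seeded 5-point multistart.  The stimulus-axis
    kernel is constrained stationary.
    """
    t_grid, e_grid, s_grid = proxy.grids()
    if e_grid is None:
        raise ValueError("non-stimulating proxy must carry electrode grids")
    # a zero jitter makes the Gaussian likelihood singular; floor it at a
    # small fraction of the proxy's overall variance
    phi2 = max(phi2, 1e-4 * float(np.var(proxy.values)), 1e-12)

    def nll_of(z):
        rho, tp, ep, lam_s = _unpack(z, with_space=True)
        try:
            kern = assemble_nonstim_kernel(
                t_grid, e_grid, s_grid, tp, ep, AxisKernelParams(lam=lam_s), rho, phi2
            )
            return neg_log_marglik(proxy.values, kern)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    if init is not None:
        z0 = _pack(init.rho, init.time, init.space, init.stim.lam)
    else:
        rho0, t0, e0, lam_s0 = _default_init(proxy, phi2, with_space=True)
        z0 = _pack(rho0, t0, e0, lam_s0)
    nll0 = nll_of(z0)
    best, n_eval = _multistart_minimize(nll_of, z0, _bounds(True), seed, n_starts)
    z = best.x if best.fun <= nll0 else z0
    rho, tp, ep, lam_s = _unpack(z, with_space=True)
    fitted = NonstimHyper(rho=rho, time=tp, space=ep, stim=AxisKernelParams(lam=lam_s), phi2=phi2)
    report = FitReport(
        nll=float(min(best.fun, nll0)),
        nll_init=float(nll0),
        converged=bool(best.success),
        n_evaluations=n_eval,
        message=str(best.message),
    )
    return fitted, report


def fit_stim_hyperparameters(
    proxy: ProxyArtifact,
    breakpoints,
    phi2_stim: float,
    seed: int = 0,
    n_starts: int = 5,
) -> tuple[StimHyper, list[FitReport]]:
    """Fit one (rho, time, stimulus) kernel per inter-breakpoint range."""
    groups = split_by_breakpoints(proxy.amplitudes, breakpoints)
    t_grid = AxisGrid(proxy.time_ms)
    phi2_stim = max(phi2_stim, 1e-4 * float(np.var(proxy.values)), 1e-12)
    ranges, reports = [], []
    for g, idx in enumerate(groups):
        sub = ProxyArtifact(
            values=proxy.values[:, idx],
            time_ms=proxy.time_ms,
            amplitudes=proxy.amplitudes[idx],
        )

        def nll_of(z, sub=sub):
            rho, tp, _, lam_s = _unpack(z, with_space=False)
            from .kernels import build_axis_kernel

            try:
                kern = KroneckerKernel(
                    rho=rho,
                    factors=[
                        build_axis_kernel(t_grid, tp),
                        build_axis_kernel(AxisGrid(sub.amplitudes), AxisKernelParams(lam=lam_s)),
                    ],
                    jitter=phi2_stim,
                )
                return neg_log_marglik(sub.values, kern)
            except (np.linalg.LinAlgError, FloatingPointError):
                return 1e12

        rho0, t0, _, lam_s0 = _default_init(sub, phi2_stim, with_space=False)
        z0 = _pack(rho0, t0, None, lam_s0)
        nll0 = nll_of(z0)
        best, n_eval = _multistart_minimize(nll_of, z0, _bounds(False), seed + g, n_starts)
        z = best.x if best.fun <= nll0 else z0
        rho, tp, _, lam_s = _unpack(z, with_space=False)
        ranges.append(StimRangeHyper(rho=rho, time=tp, stim=AxisKernelParams(lam=lam_s)))
        reports.append(
            FitReport(
                nll=float(min(best.fun, nll0)),
                nll_init=float(nll0),
                converged=bool(best.success),
                n_evaluations=n_eval,
                message=str(best.message),
            )
        )
    return StimHyper(ranges=ranges, phi2=phi2_stim), reports


def fit_model(
    datasets: list[AmplitudeSeries] | AmplitudeSeries,
    seed: int = 0,
    n_starts: int = 5,
    stim_statistic: str = "mean",
    fit_all_stim: bool = False,
) -> tuple[FittedModel, dict]:
    """End-to-end hyperparameter estimation for one or more amplitude series.

    Centers each series, pools the non-stimulating proxy across all series
    (translating each so its stimulating electrode sits at the array
    center), estimates the noise floors, and fits the non-stimulating
    kernel plus a per-range stimulating-electrode kernel.  By default the
    stimulating-electrode kernel is fitted only for the first series (the
    detection target); ``fit_all_stim`` fits one per series.  Returns the
    fitted model and a manifest of the fit.
    """
    if isinstance(datasets, AmplitudeSeries):
        datasets = [datasets]
    centered = [subtract_switching_mean(d) for d in datasets]
    proxy = build_proxy_nonstim(centered, seed=seed)
    sigma2 = float(np.mean([estimate_sigma2(c) for c in centered]))
    phi2 = estimate_phi2(
        proxy, sigma2=sigma2, n_averaged=proxy.provenance.get("n_averaged")
    )
    nonstim, report = fit_hyperparameters(proxy, phi2, seed=seed, n_starts=n_starts)

    stim: dict[int, StimHyper] = {}
    stim_reports = {}
    phi2_stim_all = []
    for c in centered if fit_all_stim else centered[:1]:
        for e in c.data.stim_electrodes:
            sproxy = build_proxy_stim(c, electrode=e, statistic=stim_statistic)
            phi2_stim = estimate_phi2(
                sproxy, sigma2=sigma2, n_averaged=sproxy.provenance.get("n_averaged")
            )
            phi2_stim_all.append(phi2_stim)
            shyper, sreps = fit_stim_hyperparameters(
                sproxy, c.data.breakpoints, phi2_stim, seed=seed, n_starts=n_starts
            )
            stim[e] = shyper
            stim_reports[e] = sreps
            phi2_stim_all[-1] = shyper.phi2  # floored value actually fitted
    noise = NoiseEstimates(
        sigma2=sigma2,
        phi2=nonstim.phi2,
        phi2_stim=float(np.mean(phi2_stim_all)) if phi2_stim_all else 0.0,
    )
    manifest = {
        "seed": seed,
        "n_starts": n_starts,
        "proxy_provenance": proxy.provenance,
        "nonstim_fit": vars(report),
        "stim_fits": {str(e): [vars(r) for r in reps] for e, reps in stim_reports.items()},
        "noise": noise.to_dict(),
    }
    return FittedModel(nonstim=nonstim, stim=stim, noise=noise), manifest
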