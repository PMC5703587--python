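"""Reference validation protocols on synthetic data.

These functions bundle the experiment designs used to validate the method:
the default desk-scale benchmark (simulate a stimulation scan, fit
hyperparameters on the pooled proxy, run the full inference on the primary
series, score against ground truth and against the mean-of-traces
baseline), the perturbation suite (trial subsampling, noise injection,
artifact magnification; full vs simplified estimator and kernel vs naive
extrapolation), hyperparameter recovery from proxies drawn from a known
kernel, and activation-threshold recovery.  The acceptance script and the
test suite both call these, so reported numbers always come from the same
code paths.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .hyper import (
    ProxyArtifact,
    estimate_sigma2,
    fit_hyperparameters,
    fit_model,
    neg_log_marglik,
    subtract_switching_mean,
)
from .infer import run_amplitude_series, run_simplified
from .kernels import AxisGrid, AxisKernelParams, assemble_nonstim_kernel
from .kron import FactoredOperator, kron_sample
from .postprocess import empirical_activation, fit_activation_cdf
from .simulate import (
    SimConfig,
    make_layout,
    perturb,
    run_baseline,
    score,
    simulate_scan,
)

__all__ = [
    "run_default_benchmark",
    "run_perturbation_suite",
    "hyperparameter_recovery",
    "activation_recovery",
]


def run_default_benchmark(seed: int = 1, config: SimConfig | None = None) -> dict:
    """Simulate the default scan, fit, detect, and score.

    Returns per-trial error rates for the full and simplified estimators,
    series-level FDR and false omission rate, the mean-of-traces baseline's
    false omission rate over the top five amplitudes (where near-
    deterministic spiking breaks that baseline), sweep-count statistics,
    and activation-threshold errors for the activated neurons.
    """
    config = config or SimConfig()
    scan = simulate_scan(config, seed=seed)
    ds = scan.primary
    model, fit_manifest = fit_model(scan.fit_series, seed=seed)

    full = run_amplitude_series(ds.data, ds.eis, model)
    simp = run_simplified(ds.data, ds.eis)
    base = run_baseline(ds.data, ds.eis)

    rep_full = score(full.spikes, ds.truth.spikes)
    rep_simp = score(simp.spikes, ds.truth.spikes)
    top5 = list(range(ds.data.J - 5, ds.data.J))
    for_full_top5 = score(full.spikes, ds.truth.spikes, amplitude_indices=top5).false_omission_rate
    for_base_top5 = score(base, ds.truth.spikes, amplitude_indices=top5).false_omission_rate

    sweeps = np.asarray(full.artifact.sweeps)

    curves = empirical_activation(full.spikes, roster=list(ds.truth.activation))
    threshold_errors = {}
    for n, curve in curves.items():
        fitted = fit_activation_cdf(
            curve.proportions, curve.counts, curve.amplitudes, neuron_id=n
        )
        mu_true = ds.truth.activation[n][0]
        if fitted.threshold is not None and not fitted.degenerate:
            threshold_errors[n] = abs(fitted.threshold - mu_true)

    return {
        "seed": seed,
        "n_trials_scored": rep_full.tp + rep_full.fp + rep_full.fn + rep_full.tn,
        "full_error_rate": rep_full.error_rate,
        "full_fdr": rep_full.fdr,
        "full_false_omission_rate": rep_full.false_omission_rate,
        "simplified_error_rate": rep_simp.error_rate,
        "baseline_for_top5": for_base_top5,
        "full_for_top5": for_full_top5,
        "sweeps": sweeps.tolist(),
        "frac_batches_leq3_sweeps": float(np.mean(sweeps <= 3)),
        "max_sweeps": int(sweeps.max()),
        "n_spikes_true": ds.truth.spikes.n_spikes(),
        "n_spikes_inferred": full.spikes.n_spikes(),
        "threshold_abs_error_uA": threshold_errors,
        "fit_nll": fit_manifest["nonstim_fit"]["nll"],
        "warnings": full.report["warnings"],
    }


def run_perturbation_suite(seeds=(1, 2, 3, 4, 5), config: SimConfig | None = None) -> dict:
    """Full-vs-simplified error orderings under data degradations.

    Conditions: trial subsampling to one trial per amplitude, injection of
    20 uV white noise (with the noise level re-estimated on the degraded
    traces, as the pipeline would), and a five-fold artifact magnification;
    under magnification the kernel-based extrapolation is additionally
    compared with naively copying the previous amplitude's artifact.
    Reports per-seed error rates and medians across seeds.
    """
    base_config = config or SimConfig()
    out = {k: {"full": [], "other": []} for k in ("trial_subsample", "noise_inject", "magnify", "extrapolation")}
    for seed in seeds:
        scan = simulate_scan(base_config, seed=seed)
        ds = scan.primary
        model, _ = fit_model(scan.fit_series, seed=seed)

        p = perturb(ds, "trial_subsample", {"k": 1}, seed=seed)
        out["trial_subsample"]["full"].append(
            score(run_amplitude_series(p.data, p.eis, model).spikes, p.truth.spikes).error_rate
        )
        out["trial_subsample"]["other"].append(
            score(run_simplified(p.data, p.eis).spikes, p.truth.spikes).error_rate
        )

        p = perturb(ds, "noise_inject", {"sigma": 20.0}, seed=seed)
        s2 = estimate_sigma2(subtract_switching_mean(p.data))
        m2 = dataclasses.replace(model, noise=dataclasses.replace(model.noise, sigma2=s2))
        out["noise_inject"]["full"].append(
            score(run_amplitude_series(p.data, p.eis, m2).spikes, p.truth.spikes).error_rate
        )
        out["noise_inject"]["other"].append(
            score(run_simplified(p.data, p.eis).spikes, p.truth.spikes).error_rate
        )

        mag_config = dataclasses.replace(base_config, magnification=5.0)
        scan5 = simulate_scan(mag_config, seed=seed)
        ds5 = scan5.primary
        m5, _ = fit_model(scan5.fit_series, seed=seed)
        full5 = score(
            run_amplitude_series(ds5.data, ds5.eis, m5).spikes, ds5.truth.spikes
        ).error_rate
        out["magnify"]["full"].append(full5)
        out["magnify"]["other"].append(
            score(run_simplified(ds5.data, ds5.eis).spikes, ds5.truth.spikes).error_rate
        )
        out["extrapolation"]["full"].append(full5)
        out["extrapolation"]["other"].append(
            score(
                run_amplitude_series(ds5.data, ds5.eis, m5, extrapolation="naive").spikes,
                ds5.truth.spikes,
            ).error_rate
        )
    for cond in out.values():
        cond["full_median"] = float(np.median(cond["full"]))
        cond["other_median"] = float(np.median(cond["other"]))
    return out


def hyperparameter_recovery(
    n_seeds: int = 10,
    seed0: int = 0,
    t_samples: int = 20,
    layout=(4, 4),
    n_amps: int = 8,
) -> dict:
    """Fit proxies drawn from a known kernel and measure recovery.

    Draws noiseless-proxy samples from a fixed non-stimulating-electrode
    kernel on a (T=20, E=16, J=8) grid, fits with the jitter held at truth,
    and reports whether the fitted likelihood reaches the truth's and
    whether the time/space inverse length-scales land within a factor of
    two of the generating values.
    """
    t_ms = np.arange(t_samples) / 20.0
    pos = make_layout(*layout, pitch=60.0)
    center = int(np.argmin(np.linalg.norm(pos - pos.mean(0), axis=1)))
    dist = np.linalg.norm(pos - pos[center], axis=1)
    amps = np.linspace(0.5, 4.0, n_amps)
    truth = {
        "rho": 8.0e5,
        "time": AxisKernelParams(lam=5.0, alpha=2.0, beta=4.0),
        "space": AxisKernelParams(lam=0.01, alpha=0.0, beta=0.005),
        "stim": AxisKernelParams(lam=0.5),
        "phi2": 2.0,
    }
    grids = (AxisGrid(t_ms), AxisGrid(pos, dist), AxisGrid(amps))
    ktrue = assemble_nonstim_kernel(
        *grids, truth["time"], truth["space"], truth["stim"], truth["rho"], truth["phi2"]
    )
    nll_ok, lam_ok, ratios = 0, 0, []
    for k in range(n_seeds):
        seed = seed0 + k
        draw = kron_sample(FactoredOperator.from_kernel(ktrue), np.random.default_rng(seed))
        proxy = ProxyArtifact(
            values=draw,
            time_ms=t_ms,
            amplitudes=amps,
            electrode_indices=np.arange(len(pos)),
            positions=pos,
            center_distance=dist,
        )
        fitted, report = fit_hyperparameters(proxy, truth["phi2"], seed=seed)
        nll_truth = neg_log_marglik(draw, ktrue)
        nll_ok += report.nll <= nll_truth + 1e-6
        r_t = fitted.time.lam / truth["time"].lam
        r_e = fitted.space.lam / truth["space"].lam
        ratios.append((r_t, r_e))
        lam_ok += (0.5 <= r_t <= 2.0) and (0.5 <= r_e <= 2.0)
    return {
        "n_seeds": n_seeds,
        "nll_leq_truth": int(nll_ok),
        "lam_within_2x": int(lam_ok),
        "lam_ratios": ratios,
    }


def activation_recovery(
    n_seeds: int = 10,
    seed0: int = 0,
    mu: float = 2.0,
    s: float = 0.3,
    n_trials: int = 50,
    amplitudes: np.ndarray | None = None,
) -> dict:
    """Threshold recovery for probit activation curves.

    Binomial spike counts are drawn from ``Phi((a - mu) / s)`` at each
    amplitude with ``n_trials`` trials, the curve is refitted, and the
    absolute threshold error is recorded per seed.
    """
    from scipy.stats import norm

    a = np.linspace(1.0, 3.0, 11) if amplitudes is None else np.asarray(amplitudes)
    p_true = norm.cdf((a - mu) / s)
    errors = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + k)
        counts = rng.binomial(n_trials, p_true)
        curve = fit_activation_cdf(counts / n_trials, np.full(a.size, n_trials), a)
        errors.append(abs(curve.threshold - mu) if curve.threshold is not None else np.inf)
    errors = np.array(errors)
    return {
        "n_seeds": n_seeds,
        "threshold_abs_errors": errors.tolist(),
        "within_0p1": int(np.sum(errors <= 0.1)),
        "median_error": float(np.median(errors)),
    }
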