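"""Activation curves, thresholds, and automatic failure diagnostics.

A neuron's *activation curve* is the proportion of trials containing one of
its spikes as a function of stimulation amplitude.  It is summarized by a
two-parameter normal-CDF (probit) fit ``p(a) = Phi((a - mu) / s)`` by
Bernoulli maximum likelihood; the neuron counts as *activated* when the
fitted curve exceeds 0.5 within the stimulated range, and its *activation
threshold* — the current eliciting a spike with probability one half — is
then exactly the fitted mean ``mu`` (since ``Phi(0) = 0.5``).

Two diagnostics flag situations a human should review: sudden jumps or drops
in the empirical activation curve (smooth monotone increase is the expected
physiology; jumps usually trace back to a wrong artifact extrapolation), and
trials whose post-fit residual power is far above the noise floor (often an
unmodeled neuron or a mismatched template).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .infer import SpikeAssignment, TemplateBank, _trial_waveform

__all__ = [
    "ActivationCurve",
    "empirical_activation",
    "fit_activation_cdf",
    "flag_activation_jump",
    "flag_residuals",
]


@dataclass
class ActivationCurve:
    """Empirical spike proportions and the fitted probit summary."""

    neuron_id: int
    amplitudes: np.ndarray
    proportions: np.ndarray
    counts: np.ndarray
    mu: float | None = None          # fitted mean, uA
    s: float | None = None           # fitted spread, uA (> 0)
    activated: bool = False
    threshold: float | None = None   # uA; defined iff activated
    degenerate: bool = False
    log_likelihood: float | None = None
    flags: dict = field(default_factory=dict)

    def fitted(self, a: np.ndarray) -> np.ndarray:
        if self.mu is None:
            raise ValueError("curve has no fit")
        return norm.cdf((np.asarray(a, dtype=float) - self.mu) / self.s)

    def to_dict(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "amplitudes": self.amplitudes.tolist(),
            "proportions": self.proportions.tolist(),
            "counts": self.counts.tolist(),
            "mu": self.mu,
            "s": self.s,
            "activated": self.activated,
            "threshold": self.threshold,
            "degenerate": self.degenerate,
            "flags": self.flags,
        }


def empirical_activation(
    spikes: SpikeAssignment,
    neuron_ids: list[int] | None = None,
    roster: list[int] | None = None,
) -> dict[int, ActivationCurve]:
    """Per-neuron spike proportions by amplitude.

    ``p_j`` is the fraction of trials at amplitude j containing at least one
    spike of the neuron.  ``neuron_ids`` defaults to the neurons that appear
    in the assignment; a requested id that appears neither there nor in the
    optional ``roster`` of known neurons is a data error.
    """
    present = sorted({n for batch in spikes.spikes for t in batch for n in t})
    if neuron_ids is None:
        neuron_ids = sorted(set(present) | set(roster or []))
    else:
        known = set(present) | set(roster or [])
        unknown = [n for n in neuron_ids if n not in known]
        if unknown:
            raise KeyError(f"unknown neuron id(s) {unknown} in activation request")
    counts = np.array([len(batch) for batch in spikes.spikes])
    out = {}
    for n in neuron_ids:
        p = np.array(
            [
                sum(1 for t in batch if n in t) / max(len(batch), 1)
                for batch in spikes.spikes
            ]
        )
        out[n] = ActivationCurve(
            neuron_id=n,
            amplitudes=np.asarray(spikes.amplitudes, dtype=float),
            proportions=p,
            counts=counts.copy(),
        )
    return out


def _bernoulli_nll(params: np.ndarray, a, k, n) -> float:
    mu, log_s = params
    s = np.exp(log_s)
    p = np.clip(norm.cdf((a - mu) / s), 1e-12, 1 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log(1 - p)).sum())


def fit_activation_cdf(
    proportions: np.ndarray,
    counts: np.ndarray,
    amplitudes: np.ndarray,
    neuron_id: int = -1,
) -> ActivationCurve:
    """Bernoulli MLE of the probit activation curve.

    The optimizer works on (mu, log s), initialized at the empirical 50%
    crossing with spread set from the stimulated range.  All-zero or all-one
    data are degenerate: activation is decided directly and no threshold is
    fitted in the all-zero case.
    """
    a = np.asarray(amplitudes, dtype=float)
    n = np.asarray(counts, dtype=float)
    p_emp = np.asarray(proportions, dtype=float)
    if len(np.unique(a)) < 2:
        raise ValueError("need at least 2 distinct amplitudes to fit an activation curve")
    k = p_emp * n
    curve = ActivationCurve(
        neuron_id=neuron_id, amplitudes=a, proportions=p_emp, counts=np.asarray(counts)
    )
    if np.all(k == 0):
        curve.activated = False
        curve.degenerate = True
        return curve
    if np.all(k == n):
        curve.activated = True
        curve.degenerate = True
        curve.threshold = float(a[0])  # activated everywhere; threshold at or below range
        return curve

    crossing = a[np.argmin(np.abs(p_emp - 0.5))]
    span = max(a[-1] - a[0], 1e-3)
    x0 = np.array([crossing, np.log(0.2 * span)])
    nll0 = _bernoulli_nll(x0, a, k, n)
    res = optimize.minimize(_bernoulli_nll, x0, args=(a, k, n), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000})
    x = res.x if res.fun <= nll0 else x0
    curve.mu = float(x[0])
    curve.s = float(np.exp(x[1]))
    curve.log_likelihood = float(-min(res.fun, nll0))
    curve.activated = bool(curve.fitted(a[-1]) >= 0.5)
    if curve.activated:
        curve.threshold = curve.mu
    return curve


def flag_activation_jump(curve: ActivationCurve, jump_tol: float = 0.5) -> tuple[bool, dict]:
    """Flag non-smooth activation: a one-step change larger than ``jump_tol``,
    or a drop by more than ``jump_tol`` after the curve has exceeded 0.5."""
    p = curve.proportions
    diffs = np.diff(p)
    jump_at = np.nonzero(np.abs(diffs) > jump_tol)[0]
    drop_after_activation = []
    seen_active = False
    for j in range(len(p) - 1):
        seen_active = seen_active or p[j] > 0.5
        if seen_active and diffs[j] < -jump_tol:
            drop_after_activation.append(j)
    flagged = bool(jump_at.size or drop_after_activation)
    details = {
        "jump_indices": jump_at.tolist(),
        "drop_after_activation": drop_after_activation,
        "max_abs_step": float(np.max(np.abs(diffs))) if diffs.size else 0.0,
    }
    curve.flags["activation_jump"] = flagged
    return flagged, details


def flag_residuals(
    traces: list[np.ndarray],
    artifacts: np.ndarray,
    spikes: SpikeAssignment,
    bank: TemplateBank,
    sigma2: float,
    z_tol: float = 4.0,
) -> list[np.ndarray]:
    """Flag trials whose residual mean square exceeds ``sigma2 * z_tol``.

    The residual is trace minus artifact minus reconstructed spikes; under a
    correct fit its power is near the noise floor, so large values indicate
    undetected or mismatched activity.  Returns one boolean array per
    amplitude.
    """
    out = []
    for j, yj in enumerate(traces):
        ms = np.array(
            [
                np.mean((yj[i] - artifacts[j] - _trial_waveform(spikes.spikes[j][i], bank)) ** 2)
                for i in range(yj.shape[0])
            ]
        )
        out.append(ms > sigma2 * z_tol)
    return out
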