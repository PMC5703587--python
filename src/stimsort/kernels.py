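"""Non-stationary covariance kernels for stimulation artifacts.

The artifact is modeled as a zero-mean Gaussian process over (time, electrode,
stimulus amplitude) whose covariance factors as a Kronecker product of one
kernel per axis.  Each axis kernel is a stationary Matérn(3/2) correlation
``K_lam`` modulated by an unnormalized gamma-density envelope ``d(x) =
x**alpha * exp(-x*beta)``, i.e. ``K = D K_lam D`` with ``D = diag(d)``.  The
envelope expresses non-stationary "bumps" in variability: artifact variance
peaks shortly after stimulus onset in time, and decays with distance from the
stimulating electrode in space.

Two assembled covariances are provided:

* non-stimulating electrodes: ``rho * K_t (x) K_e (x) K_s + phi2 * I`` with a
  stationary (alpha = beta = 0) stimulus-amplitude kernel;
* the stimulating electrode: a block-diagonal sum over stimulation ranges
  delimited by hardware breakpoints, ``sum_r rho_r * K_t^r (x) K_s^r +
  phi2p * I``, with no covariance shared across breakpoints.

Factor order is fixed package-wide as (time, electrode, stimulus); arrays are
vectorized in C (row-major) order over axes in that sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AxisKernelParams",
    "AxisGrid",
    "KroneckerKernel",
    "StimRangeBlock",
    "StimElectrodeKernel",
    "matern32",
    "gamma_envelope",
    "build_axis_kernel",
    "assemble_nonstim_kernel",
    "assemble_stim_kernel",
]

#: eigenvalues of a PSD factor may dip below zero by this relative amount
#: before we call the factor indefinite
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class AxisKernelParams:
    """Hyperparameters of one axis kernel.

    Parameters
    ----------
    lam : float
        Inverse length-scale of the Matérn(3/2) correlation, per unit of the
        axis covariate (1/ms for time, 1/um for space, 1/uA for amplitude).
    alpha, beta : float
        Shape and rate of the gamma envelope ``x**alpha * exp(-x*beta)``.
        ``alpha = beta = 0`` gives the stationary kernel.
    """

    lam: float
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"inverse length-scale must be > 0, got {self.lam}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("envelope parameters alpha, beta must be >= 0")

    def to_dict(self) -> dict:
        return {"lam": self.lam, "alpha": self.alpha, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "AxisKernelParams":
        return cls(lam=d["lam"], alpha=d.get("alpha", 0.0), beta=d.get("beta", 0.0))


@dataclass
class AxisGrid:
    """Covariate values of one axis.

    ``smooth`` enters the pairwise distance of the Matérn correlation; it may
    be 1-D (scalar covariate such as time or amplitude) or 2-D ``(n, k)``
    (positions, with Euclidean pairwise distance).  ``envelope`` is the
    nonnegative scalar covariate of the gamma envelope (time since stimulus
    onset, or distance from the stimulating electrode); it defaults to the
    smooth covariate when that is 1-D.
    """

    smooth: np.ndarray
    envelope: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.smooth = np.asarray(self.smooth, dtype=float)
        if self.envelope is None:
            if self.smooth.ndim != 1:
                raise ValueError("envelope covariate required for non-scalar smooth covariate")
            self.envelope = np.abs(self.smooth)
        self.envelope = np.asarray(self.envelope, dtype=float)
        if len(self.envelope) != len(self.smooth):
            raise ValueError(
                f"covariate length mismatch: {len(self.smooth)} smooth vs "
                f"{len(self.envelope)} envelope values"
            )
        if np.any(self.envelope < 0):
            raise ValueError("envelope covariate must be nonnegative")

    def __len__(self) -> int:
        return len(self.smooth)

    def distances(self) -> np.ndarray:
        """Pairwise distance matrix of the smooth covariate."""
        x = self.smooth
        if x.ndim == 1:
            return np.abs(x[:, None] - x[None, :])
        diff = x[:, None, :] - x[None, :, :]
        return np.sqrt((diff**2).sum(-1))


def matern32(delta, lam: float):
    """Matérn(3/2) correlation ``(1 + sqrt(3)*delta*lam) * exp(-sqrt(3)*delta*lam)``.

    The continuous analogue of an AR(2) process; equals 1 at ``delta = 0`` and
    decreases monotonically with distance.
    """
    if not lam > 0:
        raise ValueError(f"inverse length-scale must be > 0, got {lam}")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("distances must be nonnegative")
    u = np.sqrt(3.0) * delta * lam
    out = (1.0 + u) * np.exp(-u)
    return out if out.ndim else float(out)


def gamma_envelope(x, alpha: float, beta: float):
    """Unnormalized gamma density ``x**alpha * exp(-x*beta)`` with ``0**0 := 1``.

    The convention at the origin makes ``alpha = beta = 0`` exactly the
    constant envelope, so the stationary kernel is a special case.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("envelope covariate must be nonnegative")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha, beta must be >= 0")
    with np.errstate(divide="ignore"):
        out = np.where(x == 0, 1.0 if alpha == 0 else 0.0, x**alpha) * np.exp(-x * beta)
    return out if out.ndim else float(out)


def _symmetrize_psd(k: np.ndarray) -> np.ndarray:
    """Numerical PSD guard: symmetrize and check eigenvalue floor."""
    k = 0.5 * (k + k.T)
    w = np.linalg.eigvalsh(k)
    top = max(w[-1], 0.0)
    if w[0] < -PSD_RTOL * max(top, 1.0):
        raise np.linalg.LinAlgError(
            f"kernel factor is not PSD (min eigenvalue {w[0]:.3e}, max {top:.3e})"
        )
    return k


def build_axis_kernel(grid: AxisGrid, p: AxisKernelParams) -> np.ndarray:
    """Assemble one axis kernel ``D K_lam D`` on a covariate grid.

    Entry (i, k) is ``d(x_i) * matern32(|delta_i - delta_k|, lam) * d(x_k)``.
    The result is symmetric PSD (a congruence of a PSD matrix by a diagonal).
    """
    if len(grid) == 0:
        raise ValueError("empty covariate grid")
    d = gamma_envelope(grid.envelope, p.alpha, p.beta)
    k = matern32(grid.distances(), p.lam)
    return _symmetrize_psd(d[:, None] * k * d[None, :])


def _factor_eigh(factor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, q = np.linalg.eigh(0.5 * (factor + factor.T))
    return np.clip(w, 0.0, None), q


@dataclass
class KroneckerKernel:
    """Factored artifact covariance ``rho * (x)_k factors[k] + jitter * I``.

    ``factors`` are symmetric PSD matrices in the fixed axis order (time,
    electrode, stimulus); the full matrix is never materialized.  Per-factor
    eigendecompositions are cached on first use; eigenvalues of the Kronecker
    product are products of factor eigenvalues.
    """

    rho: float
    factors: list[np.ndarray]
    jitter: float = 0.0
    _eig: list[tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.rho >= 0:
            raise ValueError("rho must be >= 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        self.factors = [np.asarray(f, dtype=float) for f in self.factors]
        for f in self.factors:
            if f.ndim != 2 or f.shape[0] != f.shape[1]:
                raise ValueError("factors must be square matrices")
            _symmetrize_psd(f)

    @property
    def shape_axes(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def total_dim(self) -> int:
        return int(np.prod(self.shape_axes))

    def eig(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-factor (eigenvalues, eigenvectors), eigenvalues clipped at 0."""
        if self._eig is None:
            self._eig = [_factor_eigh(f) for f in self.factors]
        return self._eig

    def fixed_axis(self, axis: int, index: int) -> "KroneckerKernel":
        """Sub-kernel with one axis pinned to a single grid point.

        The pinned factor's diagonal entry is absorbed into the scale; the
        jitter is dropped (the caller supplies the observation shift).
        """
        diag = float(self.factors[axis][index, index])
        rest = [f for k, f in enumerate(self.factors) if k != axis]
        return KroneckerKernel(rho=self.rho * diag, factors=rest, jitter=0.0)


@dataclass
class StimRangeBlock:
    """One inter-breakpoint block of the stimulating-electrode covariance."""

    rho: float
    kt: np.ndarray
    ks: np.ndarray
    j_indices: np.ndarray  # amplitude indices of this range in the series

    def as_kron(self, jitter: float = 0.0) -> KroneckerKernel:
        return KroneckerKernel(rho=self.rho, factors=[self.kt, self.ks], jitter=jitter)


@dataclass
class StimElectrodeKernel:
    """Block-diagonal stimulating-electrode covariance over (time, stimulus).

    Covariance between amplitudes in different breakpoint ranges is exactly
    zero: hardware gain changes at breakpoints make the artifact discontinuous
    there, so no information is shared across them.
    """

    ranges: list[StimRangeBlock]
    jitter: float
    breakpoints: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        covered = np.sort(np.concatenate([b.j_indices for b in self.ranges]))
        if not np.array_equal(covered, np.arange(len(self.amplitudes))):
            raise ValueError("stimulation ranges must partition the amplitude sequence")

    def range_of(self, j: int) -> StimRangeBlock:
        for block in self.ranges:
            if j in block.j_indices:
                return block
        raise IndexError(f"amplitude index {j} not covered by any range")

    def range_index_of(self, j: int) -> int:
        for r, block in enumerate(self.ranges):
            if j in block.j_indices:
                return r
        raise IndexError(f"amplitude index {j} not covered by any range")


def split_by_breakpoints(amplitudes: np.ndarray, breakpoints) -> list[np.ndarray]:
    """Partition sorted amplitude indices into inter-breakpoint ranges."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(np.diff(amplitudes) <= 0):
        raise ValueError("amplitudes must be sorted strictly increasing")
    breakpoints = np.sort(np.asarray(breakpoints, dtype=float))
    if breakpoints.size and (
        breakpoints[0] <= amplitudes[0] or breakpoints[-1] >= amplitudes[-1]
    ):
        raise ValueError("breakpoints must lie strictly inside the amplitude range")
    edges = np.concatenate([[-np.inf], breakpoints, [np.inf]])
    groups = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = np.nonzero((amplitudes > lo) & (amplitudes <= hi))[0]
        if idx.size == 0:
            raise ValueError(
                f"breakpoint range ({lo}, {hi}] contains no stimulation amplitude"
            )
        groups.append(idx)
    return groups


def assemble_nonstim_kernel(
    t_grid: AxisGrid,
    e_grid: AxisGrid,
    s_grid: AxisGrid,
    t_params: AxisKernelParams,
    e_params: AxisKernelParams,
    s_params: AxisKernelParams,
    rho: float,
    phi2: float,
) -> KroneckerKernel:
    """Assemble the non-stimulating-electrode covariance.

    The stimulus-amplitude kernel models smoothness only (no localization),
    so its envelope parameters must be zero.
    """
    if s_params.alpha != 0 or s_params.beta != 0:
        raise ValueError("stimulus-axis kernel must be stationary (alpha = beta = 0)")
    factors = [
        build_axis_kernel(t_grid, t_params),
        build_axis_kernel(e_grid, e_params),
        build_axis_kernel(s_grid, s_params),
    ]
    return KroneckerKernel(rho=rho, factors=factors, jitter=phi2)


def assemble_stim_kernel(
    t_grid: AxisGrid,
    amplitudes: np.ndarray,
    breakpoints,
    params_per_range: list[dict],
    phi2p: float,
) -> StimElectrodeKernel:
    """Assemble the stimulating-electrode covariance, one block per range.

    ``params_per_range`` holds one ``{"rho", "time": AxisKernelParams,
    "stim": AxisKernelParams}`` entry per inter-breakpoint range, in
    increasing amplitude order.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    groups = split_by_breakpoints(amplitudes, breakpoints)
    if len(params_per_range) != len(groups):
        raise ValueError(
            f"expected {len(groups)} per-range parameter sets, got {len(params_per_range)}"
        )
    blocks = []
    for idx, p in zip(groups, params_per_range):
        sp = p["stim"]
        if sp.alpha != 0 or sp.beta != 0:
            raise ValueError("stimulus-axis kernel must be stationary (alpha = beta = 0)")
        blocks.append(
            StimRangeBlock(
                rho=p["rho"],
                kt=build_axis_kernel(t_grid, p["time"]),
                ks=build_axis_kernel(AxisGrid(amplitudes[idx]), sp),
                j_indices=idx,
            )
        )
    return StimElectrodeKernel(
        ranges=blocks,
        jitter=phi2p,
        breakpoints=np.sort(np.asarray(breakpoints, dtype=float)),
        amplitudes=amplitudes,
    )
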