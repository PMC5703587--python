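"""Scalable linear algebra for Kronecker-factored covariances.

Every operation here (matrix-vector products, shifted solves, log
determinants, sampling, GP conditioning, posterior filtering) works on the
per-factor eigendecompositions, so the cost is cubic in the largest factor
dimension rather than in the total dimension.  Dense matrices of the full
size are only ever formed by :func:`dense`, which refuses above a
densification cap — this keeps the engine honest about scalability and is
relied on by the oracle tests.

Vectorization convention: a vector of length ``prod(sizes)`` corresponds to a
C-ordered (row-major) array whose axes follow the factor order of the kernel
(time, electrode, stimulus).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .kernels import KroneckerKernel

__all__ = [
    "FactoredOperator",
    "kron_matvec",
    "kron_solve_shifted",
    "kron_logdet_shifted",
    "kron_sample",
    "kron_conditional_mean",
    "posterior_filter",
    "dense",
]

#: largest total dimension for which dense() will materialize the full matrix
DENSIFICATION_CAP = 4096

# eigendecompositions are cached by factor content so the inference loop can
# rebuild operators per amplitude without re-diagonalizing shared factors
_EIG_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}
_EIG_CACHE_MAX = 256


def _eigh_cached(factor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    key = hashlib.sha1(np.ascontiguousarray(factor).tobytes()).hexdigest()
    hit = _EIG_CACHE.get(key)
    if hit is None:
        sym = 0.5 * (factor + factor.T)
        w, q = np.linalg.eigh(sym)
        hit = (np.clip(w, 0.0, None), q)
        if len(_EIG_CACHE) >= _EIG_CACHE_MAX:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = hit
    return hit


def kron_matvec(factors: list[np.ndarray], v: np.ndarray) -> np.ndarray:
    """Product ``kron(factors) @ v`` without forming the Kronecker product.

    Factors may be rectangular; ``v`` must have length equal to the product
    of factor column counts.  Returns a vector of length equal to the product
    of factor row counts.
    """
    factors = [np.asarray(f, dtype=float) for f in factors]
    cols = [f.shape[1] for f in factors]
    v = np.asarray(v, dtype=float)
    if v.size != int(np.prod(cols)):
        raise ValueError(f"vector of length {v.size} incompatible with factor columns {cols}")
    x = v.reshape(cols)
    for k, f in enumerate(factors):
        x = np.moveaxis(np.tensordot(f, x, axes=([1], [k])), 0, k)
    return x.reshape(-1)


@dataclass
class FactoredOperator:
    """The shifted operator ``rho * kron(factors) + shift * I``.

    ``shift`` is the total additive diagonal (the artifact jitter ``phi2``,
    the per-trial observation noise ``sigma2/n_j``, or their sum, depending
    on which matrix of the model is being represented).
    """

    rho: float
    factors: list[np.ndarray]
    shift: float = 0.0
    _eig: list[tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    @classmethod
    def from_kernel(cls, kernel: KroneckerKernel, extra_shift: float = 0.0) -> "FactoredOperator":
        """Wrap a kernel; its jitter plus ``extra_shift`` form the diagonal."""
        return cls(rho=kernel.rho, factors=list(kernel.factors),
                   shift=kernel.jitter + extra_shift)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def total_dim(self) -> int:
        return int(np.prod(self.sizes))

    def eig(self) -> list[tuple[np.ndarray, np.ndarray]]:
        if self._eig is None:
            self._eig = [_eigh_cached(f) for f in self.factors]
        return self._eig

    def eigenvalues(self) -> np.ndarray:
        """All ``rho * prod_k w_k + shift`` as an array shaped like the axes."""
        kappa = np.ones(())
        for w, _ in self.eig():
            kappa = np.multiply.outer(kappa, w)
        return self.rho * kappa + self.shift

    def _to_eigenbasis(self, x: np.ndarray) -> np.ndarray:
        return kron_matvec([q.T for _, q in self.eig()], x.reshape(-1)).reshape(self.sizes)

    def _from_eigenbasis(self, x: np.ndarray) -> np.ndarray:
        return kron_matvec([q for _, q in self.eig()], x.reshape(-1)).reshape(self.sizes)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).reshape(-1)
        return self.rho * kron_matvec(self.factors, v) + self.shift * v


def kron_solve_shifted(op: FactoredOperator, v: np.ndarray) -> np.ndarray:
    """Solve ``(rho * kron(factors) + shift * I) x = v`` in the eigenbasis."""
    v = np.asarray(v, dtype=float)
    shape = v.shape
    lam = op.eigenvalues()
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError(
            "operator is singular: some total eigenvalues are <= 0 "
            f"(min {lam.min():.3e}); a positive shift is required"
        )
    z = op._to_eigenbasis(v.reshape(-1))
    return op._from_eigenbasis(z / lam).reshape(shape)


def kron_logdet_shifted(op: FactoredOperator) -> float:
    """``log|rho * kron(factors) + shift * I|`` from factor eigenvalues."""
    lam = op.eigenvalues()
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError("nonpositive eigenvalue in shifted operator")
    return float(np.sum(np.log(lam)))


def kron_sample(op: FactoredOperator, rng: np.random.Generator | int) -> np.ndarray:
    """Zero-mean Gaussian draw with covariance ``rho * kron(factors) + shift * I``.

    Implemented as independent linear filters in each direction: start from
    i.i.d. standard normals in the eigenbasis, scale by the square-root
    eigenvalues of the structured part, rotate back, and add white noise for
    the diagonal shift.  Returns an array shaped like the factor axes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kappa = np.ones(())
    for w, _ in op.eig():
        kappa = np.multiply.outer(kappa, w)
    z = rng.standard_normal(op.sizes)
    structured = op._from_eigenbasis(np.sqrt(op.rho * kappa) * z)
    if op.shift > 0:
        structured = structured + np.sqrt(op.shift) * rng.standard_normal(op.sizes)
    return structured


def posterior_filter(kernel: KroneckerKernel, x: np.ndarray, noise: float) -> np.ndarray:
    """GP posterior mean ``K (K + noise * I)^-1 x`` for observations ``x``.

    In the kernel eigenbasis each component shrinks by ``kappa / (kappa +
    noise)``; with ``noise = 0`` the input is returned unchanged (the filter
    converges to the identity).  ``kernel.jitter`` is ignored here — the
    caller passes the full observation noise explicitly.
    """
    x = np.asarray(x, dtype=float)
    op = FactoredOperator(rho=kernel.rho, factors=list(kernel.factors), shift=0.0)
    if x.size != op.total_dim:
        raise ValueError(f"input of size {x.size} incompatible with kernel axes {op.sizes}")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if noise == 0:
        return x.copy()
    kappa = np.ones(())
    for w, _ in op.eig():
        kappa = np.multiply.outer(kappa, w)
    kappa = op.rho * kappa
    z = op._to_eigenbasis(x.reshape(-1))
    return op._from_eigenbasis(z * (kappa / (kappa + noise))).reshape(x.shape)


def kron_conditional_mean(
    kernel: KroneckerKernel,
    obs_indices: np.ndarray,
    target_indices: np.ndarray,
    observed: np.ndarray,
    obs_noise: float,
    axis: int = -1,
) -> np.ndarray:
    """GP conditional mean along one factor axis (the stimulus axis).

    Computes ``K_(target,obs) (K_(obs,obs) + obs_noise * I)^-1 observed``
    where the index sets select slices along ``axis`` of the kernel; both
    sub-blocks inherit the Kronecker structure, so the solve stays factored.
    ``observed`` is shaped like the kernel axes with ``axis`` restricted to
    ``obs_indices``; the result has that axis restricted to
    ``target_indices``.
    """
    obs_indices = np.asarray(obs_indices, dtype=int)
    target_indices = np.asarray(target_indices, dtype=int)
    if obs_indices.size == 0:
        raise ValueError("observed index set is empty")
    axis = axis % len(kernel.factors)
    f_ax = kernel.factors[axis]

    sub_factors = [
        f_ax[np.ix_(obs_indices, obs_indices)] if k == axis else f
        for k, f in enumerate(kernel.factors)
    ]
    op = FactoredOperator(rho=kernel.rho, factors=sub_factors, shift=obs_noise)
    if obs_noise == 0:
        # numerical guard: PSD factors may have eigenvalues clipped to zero,
        # so a noise-free solve gets a relative jitter floor instead
        top = kernel.rho * float(np.prod([w.max() for w, _ in op.eig()]))
        op = FactoredOperator(rho=kernel.rho, factors=sub_factors, shift=1e-12 * max(top, 1.0))
    observed = np.asarray(observed, dtype=float)
    if observed.shape != op.sizes:
        raise ValueError(f"observed block has shape {observed.shape}, expected {op.sizes}")
    alpha = kron_solve_shifted(op, observed)

    cross_factors = [
        f_ax[np.ix_(target_indices, obs_indices)] if k == axis else f
        for k, f in enumerate(kernel.factors)
    ]
    out_sizes = tuple(
        len(target_indices) if k == axis else f.shape[0]
        for k, f in enumerate(kernel.factors)
    )
    return kernel.rho * kron_matvec(cross_factors, alpha.reshape(-1)).reshape(out_sizes)


def dense(op: FactoredOperator | KroneckerKernel) -> np.ndarray:
    """Materialize the full covariance matrix (oracle/debug use only).

    Refuses above :data:`DENSIFICATION_CAP` so that production code paths can
    never silently fall back to dense algebra.
    """
    if isinstance(op, KroneckerKernel):
        op = FactoredOperator.from_kernel(op)
    n = op.total_dim
    if n > DENSIFICATION_CAP:
        raise MemoryError(
            f"refusing to materialize a {n} x {n} covariance "
            f"(densification cap {DENSIFICATION_CAP})"
        )
    full = np.ones((1, 1))
    for f in op.factors:
        full = np.kron(full, f)
    return op.rho * full + op.shift * np.eye(n)
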