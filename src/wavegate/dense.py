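"""Dense (non-convolutional) 1D unitary networks and localization diagnostics.

Dropping translational invariance: the generator is an N x N anti-Hermitian
matrix A built as a circulant wave part (a 1D wave kernel, default
i.[1, -2, 1]) plus random complex Gaussian bands at offsets +-1, +-2, +-3
scaled by ``rho``, wrapped periodically.  The negative bands are the negated
conjugate transpose of the positive ones, so A^dagger = -A holds exactly and
U = expm(A) is unitary.

Local random couplings in 1D produce Anderson localization: some eigenvectors
of the coupling collapse onto finite regions and stop supporting global
traveling waves.  The participation ratio PR(v) = 1 / sum |v_i|^4 (for unit
eigenvectors) measures the effective support; ``spanning_fraction`` counts
eigenvectors with PR above a cut (default N/4).  At rho = 0 every eigenvector
is a plane wave (PR >= 2N/3); at large rho almost all are localized.
``tune_rho_for_half_spanning`` bisects rho to the regime where about half the
spectrum spans the system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .dynamics import InputSchedule, evolve
from .kernels import circulant_from_wrapped, embed_kernel

__all__ = [
    "DenseCoupling",
    "SpectrumDiagnostics",
    "build_dense_coupling",
    "evolve_dense",
    "localization_diagnostics",
    "tune_rho_for_half_spanning",
]

_RANDOM_OFFSETS = (1, 2, 3)


def _default_wave_kernel() -> np.ndarray:
    return 1j * np.array([1.0, -2.0, 1.0])


@dataclass(frozen=True)
class DenseCoupling:
    """Banded anti-Hermitian generator A and its unitary exponential U."""

    A: np.ndarray = field(repr=False)
    U: np.ndarray = field(repr=False)
    rho: float
    seed: int

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def lattice_shape(self) -> tuple:
        return (self.N,)

    def apply(self, Z: np.ndarray) -> np.ndarray:
        return self.U @ np.asarray(Z)


def build_dense_coupling(
    N: int, wave_kernel=None, rho: float = 0.0, seed: int = 0
) -> DenseCoupling:
    """Assemble A = circulant(wave kernel) + rho * (random bands), U = expm(A).

    The random bands sit at offsets +1, +2, +3 (i.i.d. standard complex
    Gaussians, periodic wrap) with the -k band set to the negated conjugate
    transpose, making A exactly anti-Hermitian for every rho and seed.
    """
    if N < 8:
        raise ValueError("N must be >= 8")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    wk = _default_wave_kernel() if wave_kernel is None else np.asarray(wave_kernel, complex)
    A = circulant_from_wrapped(embed_kernel(wk, (N,)))
    if rho > 0:
        rng = np.random.default_rng(seed)
        B = np.zeros((N, N), dtype=complex)
        i = np.arange(N)
        for k in _RANDOM_OFFSETS:
            g = (rng.standard_normal(N) + 1j * rng.standard_normal(N)) / np.sqrt(2)
            B[i, (i + k) % N] = g
        A = A + rho * (B - B.conj().T)
    U = expm(A)
    return DenseCoupling(A=A, U=U, rho=float(rho), seed=int(seed))


def evolve_dense(Z0, coupling: DenseCoupling, schedule: InputSchedule, n_steps: int,
                 record_every: int | None = None, observer=None):
    """Iterate Z <- phi(U Z + I_n); same contract as :func:`dynamics.evolve`."""
    return evolve(Z0, coupling, schedule, n_steps, record_every=record_every,
                  observer=observer)


@dataclass(frozen=True)
class SpectrumDiagnostics:
    """Eigen-spectrum of the coupling with localization measures."""

    eigenvalues: np.ndarray  # of U, on the unit circle
    participation_ratios: np.ndarray  # in [1, N]
    spanning_fraction: float
    spanning_cut: float


def localization_diagnostics(
    coupling: DenseCoupling, spanning_cut: float | None = None
) -> SpectrumDiagnostics:
    """Eigendecompose the generator and measure eigenvector localization.

    ``i A`` is Hermitian, so the decomposition uses the symmetric
    eigensolver; eigenvalues of U are exp(-i omega) for the real frequencies
    omega of i A.  ``spanning_cut`` defaults to N/4: eigenvectors with
    participation ratio above it count as system-spanning.
    """
    N = coupling.N
    if N > 4096:
        raise ValueError("dense eigendecomposition guarded to N <= 4096")
    if spanning_cut is None:
        spanning_cut = N / 4.0
    omega, V = np.linalg.eigh(1j * coupling.A)
    pr = 1.0 / np.sum(np.abs(V) ** 4, axis=0)
    return SpectrumDiagnostics(
        eigenvalues=np.exp(-1j * omega),
        participation_ratios=pr,
        spanning_fraction=float(np.mean(pr > spanning_cut)),
        spanning_cut=float(spanning_cut),
    )


def _mean_spanning(N, wave_kernel, rho, seeds, spanning_cut):
    fracs = [
        localization_diagnostics(
            build_dense_coupling(N, wave_kernel, rho=rho, seed=s),
            spanning_cut=spanning_cut,
        ).spanning_fraction
        for s in seeds
    ]
    return float(np.mean(fracs))


def tune_rho_for_half_spanning(
    N: int,
    wave_kernel=None,
    seeds=(0, 1, 2, 3, 4),
    target: tuple = (0.4, 0.6),
    rho_lo: float = 1e-3,
    rho_hi: float = 2.0,
    spanning_cut: float | None = None,
    max_iter: int = 40,
) -> float:
    """Bisect rho until the seed-averaged spanning fraction lands in ``target``.

    The spanning fraction is ~1 at rho -> 0 and falls toward 0 as disorder
    grows; bisection needs the endpoints to bracket the target band
    (``rho_hi`` is doubled a few times if not).  Failure to bracket raises
    with the sweep table.
    """
    lo, hi = float(rho_lo), float(rho_hi)
    f_lo = _mean_spanning(N, wave_kernel, lo, seeds, spanning_cut)
    f_hi = _mean_spanning(N, wave_kernel, hi, seeds, spanning_cut)
    sweep = [(lo, f_lo), (hi, f_hi)]
    tries = 0
    while f_hi > target[1] and tries < 6:
        hi *= 2.0
        f_hi = _mean_spanning(N, wave_kernel, hi, seeds, spanning_cut)
        sweep.append((hi, f_hi))
        tries += 1
    if f_lo < target[0] or f_hi > target[1]:
        raise RuntimeError(
            f"cannot bracket spanning fraction {target}; sweep: {sweep}"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log rho: disorder acts multiplicatively
        f_mid = _mean_spanning(N, wave_kernel, mid, seeds, spanning_cut)
        sweep.append((mid, f_mid))
        if target[0] <= f_mid <= target[1]:
            return float(mid)
        if f_mid > target[1]:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"bisection did not land in {target}; sweep: {sweep}")
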