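"""Closed-form and simulated response to a point tone.

Under a uniform attenuation gamma < 1, a tone alpha * lambda^n injected at a
single site drives the linearized network into a periodic steady state
dZ_n = R* lambda^n whose envelope solves R* lambda = gamma (U (x) R* + alpha
delta).  In Fourier space this is an element-wise division:

    F[R*] = alpha F[delta] / (lambda/gamma - F[U]).

As gamma -> 1 with lambda at an eigenvalue of U the denominator develops a
pole: the linear response diverges and the nonlinear network takes over,
saturating at an amplitude that scales like the cubic root of alpha (the
hallmark of forcing a Hopf-critical system at resonance).  Off resonance the
response stays linear in alpha and decays exponentially in space away from
the injection site.

``resonance_scaling_probe`` measures the nonlinear steady amplitude by full
simulation: it demodulates the trailing state at the forcing frequency and
declares steadiness when consecutive windowed amplitudes agree to 1%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import phi
from .kernels import UnitaryKernel

__all__ = [
    "PoleError",
    "LinearResponse",
    "closed_form_response",
    "largest_gap_frequency",
    "resonance_scaling_probe",
]


class PoleError(ValueError):
    """Raised when lambda/gamma lies (numerically) on the spectrum of U."""


@dataclass(frozen=True)
class LinearResponse:
    """Asymptotic envelope R* of the linear response to a point tone."""

    R_star: np.ndarray
    lam: complex
    gamma_scalar: float
    alpha: float
    site: tuple
    residual: float  # sup-norm defect of R* lam = gamma (U(x)R* + alpha delta)


def closed_form_response(
    U: UnitaryKernel,
    lam: complex,
    gamma_scalar: float,
    alpha: float,
    site,
    pole_guard: float = 1e-8,
) -> LinearResponse:
    """Solve the steady linear response by Fourier division.

    Raises :class:`PoleError` when min |lambda/gamma - F[U]| < ``pole_guard``
    (the division would blow up); the error reports the distance from lambda
    to the nearest eigenvalue of U.
    """
    lam = complex(lam)
    if abs(abs(lam) - 1.0) > 1e-9:
        raise ValueError("forcing frequency lambda must have unit modulus")
    if not (0 < gamma_scalar <= 1):
        raise ValueError("gamma must be in (0, 1]")
    site = tuple(np.atleast_1d(site).astype(int))
    denom = lam / gamma_scalar - U.spectrum
    min_dist = float(np.min(np.abs(denom)))
    if min_dist < pole_guard:
        near = float(np.min(np.abs(lam - U.spectrum)))
        raise PoleError(
            f"lambda/gamma within {min_dist:.3g} of the spectrum of U (pole);"
            f" distance from lambda to nearest eigenvalue: {near:.3g}"
        )
    delta = np.zeros(U.lattice_shape, dtype=complex)
    delta[site] = alpha
    R = np.fft.ifftn(np.fft.fftn(delta) / denom)
    residual = float(
        np.max(np.abs(R * lam - gamma_scalar * (U.apply(R) + delta)))
    )
    return LinearResponse(
        R_star=R, lam=lam, gamma_scalar=float(gamma_scalar), alpha=float(alpha),
        site=site, residual=residual,
    )


def largest_gap_frequency(U: UnitaryKernel) -> complex:
    """Unit-modulus frequency at the middle of the largest gap in arg F[U].

    The most off-resonant tone available on this lattice: maximally far (in
    angle) from every eigenvalue of U.
    """
    angles = np.sort(np.angle(U.spectrum.ravel()))
    gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
    i = int(np.argmax(gaps))
    mid = angles[i] + gaps[i] / 2.0
    return complex(np.exp(1j * mid))


def _neighborhood(site, radius, shape):
    idx = np.ix_(
        *[
            (np.arange(s - radius, s + radius + 1) % n)
            for s, n in zip(site, shape)
        ]
    )
    return idx


def resonance_scaling_probe(
    U: UnitaryKernel,
    lam: complex,
    alphas,
    site=None,
    neighborhood_radius: int = 2,
    window: int = 512,
    max_steps: int = 400_000,
    steady_rtol: float = 0.01,
) -> list[float]:
    """Steady nonlinear response magnitudes of the full map to a point tone.

    For each amplitude alpha, iterates Z <- phi(U(x)Z + alpha lambda^n delta)
    from Z = 0 (no design input, Gamma == 1) until steady, and records the RMS
    over a small neighborhood of the injection site of the amplitude
    demodulated at the forcing frequency over the trailing window.

    Steadiness: consecutive window amplitudes within ``steady_rtol`` relative.
    Exceeding ``max_steps`` without steadiness raises RuntimeError.

    With lambda an exact eigenvalue of U the returned magnitudes scale as
    alpha^(1/3) (resonant cubic-root compression); far off resonance, and at
    amplitudes small enough to stay linear, they scale as alpha.
    """
    lam = complex(lam)
    shape = U.lattice_shape
    if site is None:
        site = tuple(s // 2 for s in shape)
    site = tuple(int(x) for x in np.atleast_1d(site))
    nbhd = _neighborhood(site, neighborhood_radius, shape)
    out = []
    for alpha in alphas:
        alpha = float(alpha)
        if alpha == 0.0:
            out.append(0.0)
            continue
        Z = np.zeros(shape, dtype=complex)
        phase = 1.0 + 0j
        conj_lam = np.conj(lam)
        acc = np.zeros_like(Z[nbhd])
        prev = None
        steady = None
        n = 0
        while n < max_steps:
            buf = U.apply(Z)
            buf[site] += alpha * phase
            Z = phi(buf)
            phase *= lam
            # demodulate: average Z * conj(lam)^n over the window
            acc += Z[nbhd] * np.conj(phase)
            n += 1
            if n % window == 0:
                amp = float(np.sqrt(np.mean(np.abs(acc / window) ** 2)))
                acc[...] = 0.0
                if prev is not None and abs(amp - prev) <= steady_rtol * max(prev, 1e-300):
                    steady = amp
                    break
                prev = amp
        if steady is None:
            raise RuntimeError(
                f"response not steady within {max_steps} steps at alpha={alpha:g}"
                f" (last window amplitudes {prev!r})"
            )
        out.append(steady)
    return out
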