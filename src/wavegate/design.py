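"""Inverse design: from a target attenuation map to the input that realizes it.

The central construction of the package.  A constant input I* drives the
network into a steady ongoing activity Z* = phi(U (x) Z* + I*), and small
waves riding on that background are attenuated per site by

    Gamma = phi'( U (x) Z* + I* ).

Given a *desired* Gamma (all values in (0, 1]), the inversion proceeds by
solving phi'(w) = Gamma for the operating point, w = sqrt(Gamma^(-2/3) - 1)
(nonnegative real branch), whence

    Z* = phi(w),        I* = w - U (x) Z*,

and Z* is then an exact fixed point of the full map by construction.  The
dense (non-convolutional) variant replaces the convolution by multiplication
with a unitary matrix.

Gamma > 1 has no real solution for this sigmoid (the square root turns
imaginary) and is rejected here; supercritical dynamics are handled by
``dynamics.modulated_step`` instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import phi, phi_inverse, phi_prime

__all__ = ["DesignResult", "design_input", "design_input_dense", "realized_attenuation"]


@dataclass(frozen=True)
class DesignResult:
    """The pair (Z*, I*) realizing a requested attenuation map.

    ``realized_gamma`` is phi'(U(x)Z* + I*) recomputed from the pair;
    ``max_residual`` is the sup-norm mismatch between realized and requested
    Gamma, and ``fp_residual`` the sup-norm defect of the fixed-point equation
    Z* = phi(U(x)Z* + I*).  Both are round-off sized for valid inputs.
    """

    z_star: np.ndarray
    i_star: np.ndarray
    realized_gamma: np.ndarray
    max_residual: float
    fp_residual: float


def _validate_gamma(gamma) -> np.ndarray:
    gamma = np.asarray(gamma, dtype=float)
    if np.any(~np.isfinite(gamma)):
        raise ValueError("attenuation map contains non-finite values")
    if np.any(gamma <= 0):
        raise ValueError("attenuation map must be > 0 everywhere")
    if np.any(gamma > 1):
        raise ValueError(
            "attenuation map exceeds 1: exact inversion is impossible for this"
            f" sigmoid (max Gamma = {gamma.max():.6g}); supercritical maps are"
            " handled by dynamics.modulated_step"
        )
    return gamma


def _operating_point(gamma: np.ndarray) -> np.ndarray:
    # w = sqrt(Gamma^(-2/3) - 1); clip the tiny negative round-off at Gamma = 1
    return np.sqrt(np.maximum(gamma ** (-2.0 / 3.0) - 1.0, 0.0))


def _finish(z_star, i_star, gamma, applied):
    arg = applied + i_star
    realized = phi_prime(arg)
    return DesignResult(
        z_star=z_star,
        i_star=i_star,
        realized_gamma=realized,
        max_residual=float(np.max(np.abs(realized - gamma))),
        fp_residual=float(np.max(np.abs(phi(arg) - z_star))),
    )


def design_input(gamma, U) -> DesignResult:
    """Invert an attenuation map through the convolution kernel ``U``.

    Parameters
    ----------
    gamma : array, values in (0, 1]
        Requested per-site attenuation, same shape as the lattice.
    U : UnitaryKernel
        The coupling the design must work against (I* depends on it).
    """
    gamma = _validate_gamma(gamma)
    if tuple(gamma.shape) != tuple(U.lattice_shape):
        raise ValueError(
            f"gamma shape {gamma.shape} does not match lattice {U.lattice_shape}"
        )
    w = _operating_point(gamma)
    z_star = phi(w)
    applied = U.apply(z_star)
    i_star = w - applied
    return _finish(z_star, i_star, gamma, applied)


def design_input_dense(gamma, U_dense) -> DesignResult:
    """Dense-network variant: ``Z* = phi(w)``, ``I* = phi^-1(Z*) - U Z*``.

    ``U_dense`` is an N x N unitary matrix (or a DenseCoupling, whose ``U`` is
    used); ``gamma`` a 1D map of length N.
    """
    U = getattr(U_dense, "U", U_dense)
    U = np.asarray(U)
    gamma = _validate_gamma(gamma)
    if gamma.ndim != 1 or gamma.shape[0] != U.shape[0]:
        raise ValueError(
            f"gamma shape {gamma.shape} does not match matrix of size {U.shape}"
        )
    w = _operating_point(gamma)
    z_star = phi(w)
    applied = U @ z_star
    i_star = phi_inverse(z_star) - applied
    return _finish(z_star, i_star, gamma, applied)


def realized_attenuation(z_star, i_star, U) -> np.ndarray:
    """Attenuation actually produced by a fixed-point pair (Z*, I*).

    Returns phi'(U(x)Z* + I*).  For a true fixed point this equals
    phi'(phi^-1(Z*)) — the equality is a consistency check on the pair — which
    requires |Z*| < 1 everywhere (range of phi); violation raises.
    """
    z_star = np.asarray(z_star)
    if np.any(np.abs(z_star) >= 1):
        raise ValueError("|Z*| >= 1 somewhere: not in the range of phi")
    apply = U.apply if hasattr(U, "apply") else (lambda Z: np.asarray(U) @ Z)
    return phi_prime(apply(z_star) + np.asarray(i_star))
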