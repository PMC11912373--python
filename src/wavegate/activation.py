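"""Phase-preserving sigmoid activation and its scalar fixed-point theory.

The network nonlinearity is the complex sigmoid

    phi(z) = z / sqrt(1 + |z|^2)

which fixes the origin (phi(0) = 0), has unit slope there (phi'(0) = 1) and is
strictly contracting everywhere else.  These three properties are what place the
network at a critical point: the linearization around the quiescent state is
exactly the unitary coupling, with all eigenvalues on the unit circle.

"Derivative" here always means the radial slope

    phi'(z) = (1 + |z|^2)^(-3/2),

a real number in (0, 1]; phi is not holomorphic and no complex Jacobian is used
anywhere in the package.  The per-site value of this slope at the operating
point is the attenuation Gamma that gates wave propagation.

The scalar (single-neuron) recurrence z <- phi(z + I) exposes the singular
input sensitivity of the critical point: for small real input I the fixed point
grows like the cubic root, z* ~ (2 I)^(1/3), the slope at the fixed point is
gamma = phi'(z* + I), and the relaxation time tau = -1/ln(gamma) diverges like
(2/3) (2 I)^(-2/3) as I -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "phi",
    "phi_prime",
    "phi_inverse",
    "scalar_fixed_point",
    "ScalarFixedPoint",
]


def _as_finite_array(z, name: str = "z") -> np.ndarray:
    z = np.asarray(z)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite values in {name}: invalid network state")
    return z


def _maybe_scalar(out: np.ndarray, like) -> np.ndarray | complex | float:
    # return a python scalar when the input was scalar-like
    if np.ndim(like) == 0:
        return out[()]
    return out


def phi(z):
    """Phase-preserving sigmoid ``z / sqrt(1 + |z|^2)``, element-wise.

    Maps the complex plane onto the open unit disk, preserving the complex
    phase of every entry.  Accepts scalars or arrays of any shape.
    """
    z = _as_finite_array(z)
    out = z / np.sqrt(1.0 + np.abs(z) ** 2)
    return _maybe_scalar(out, z)


def phi_prime(z):
    """Radial slope of :func:`phi`: ``(1 + |z|^2)^(-3/2)``, element-wise.

    Real-valued, in (0, 1]; equals 1 only at z = 0.  This is the per-site
    attenuation factor experienced by small perturbations around an operating
    point z.
    """
    z = _as_finite_array(z)
    out = (1.0 + np.abs(z) ** 2) ** (-1.5)
    return _maybe_scalar(out, z)


def phi_inverse(w):
    """Inverse sigmoid ``w / sqrt(1 - |w|^2)``; defined for |w| < 1.

    Raises
    ------
    ValueError
        If any entry has modulus >= 1 (the pole of the inverse); the message
        identifies the offending site(s).
    """
    w = _as_finite_array(w, "w")
    a2 = np.abs(w) ** 2
    bad = a2 >= 1.0
    if np.any(bad):
        sites = np.argwhere(np.atleast_1d(bad))[:8].tolist()
        raise ValueError(
            f"phi_inverse domain error: |w| >= 1 at site(s) {sites}"
            f" (max |w| = {np.sqrt(a2.max()):.6g})"
        )
    out = w / np.sqrt(1.0 - a2)
    return _maybe_scalar(out, w)


@dataclass(frozen=True)
class ScalarFixedPoint:
    """Fixed point of the single-neuron recurrence ``z <- phi(z + I)``.

    Attributes
    ----------
    input_I : complex
        The constant input.
    z_star : complex
        The fixed point, satisfying ``z_star = phi(z_star + I)``.
    gamma : float
        Slope of phi at the operating point, ``phi'(z_star + I)``; in (0, 1].
    tau : float
        Relaxation time in steps, ``-1/ln(gamma)``; ``inf`` at gamma = 1
        (which happens iff I = 0, where relaxation is algebraic).
    """

    input_I: complex
    z_star: complex
    gamma: float
    tau: float


def scalar_fixed_point(I, tol: float = 1e-12, max_iter: int = 10**6) -> ScalarFixedPoint:
    """Solve the scalar fixed point ``z* = phi(z* + I)`` by plain iteration.

    The map is globally contracting (Banach), so iteration from z = 0
    converges for every finite I.  For small real I the solution obeys the
    asymptotics z* ~ (2I)^(1/3) and tau ~ (2/3)(2I)^(-2/3).

    Parameters
    ----------
    I : complex
        Constant scalar input (typically real, >= 0).
    tol : float
        Stop when successive iterates differ by less than this.
    max_iter : int
        Iteration budget; exceeded -> RuntimeError reporting the last iterate.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    I = complex(I)
    if not (math.isfinite(I.real) and math.isfinite(I.imag)):
        raise ValueError("non-finite input I")
    if I == 0:
        return ScalarFixedPoint(input_I=I, z_star=0j, gamma=1.0, tau=math.inf)

    z = 0j
    for _ in range(max_iter):
        w = z + I
        zn = w / math.sqrt(1.0 + w.real * w.real + w.imag * w.imag)
        if abs(zn - z) < tol:
            z = zn
            break
        z = zn
    else:
        raise RuntimeError(
            f"scalar fixed point did not converge within {max_iter} iterations"
            f" (last iterate {z!r}, last step {abs(zn - z):.3g})"
        )

    w = z + I
    gamma = (1.0 + abs(w) ** 2) ** (-1.5)
    tau = math.inf if gamma >= 1.0 else -1.0 / math.log(gamma)
    return ScalarFixedPoint(input_I=I, z_star=z, gamma=gamma, tau=tau)
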