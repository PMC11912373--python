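"""Time evolution of the network and of its linearization.

The full nonlinear map is

    Z_{n+1} = phi( U (x) Z_n + I_n ),

iterated with the convolution done by spectrum multiplication in Fourier
space.  Inputs are composite: a constant part I* (the "circuit drawing"),
point sources (tones alpha * lambda^n or seeded complex white noise at a
site), and an optional time-dependent hook (used e.g. for slowly moving
boundary conditions).

Around an operating point Z* with attenuation map Gamma = phi'(U(x)Z* + I*),
small perturbations obey the linear map

    dZ_{n+1} = Gamma . ( U (x) dZ_n + forcing_n )

(element-wise product with Gamma; the forcing enters inside the slope factor
because it enters the argument of phi).  With Gamma == 1 this map is unitary;
with Gamma == g < 1 uniform the norm contracts by exactly g per step.

``modulated_step`` is the saturating variant phi(Gamma . (U (x) dZ)) used for
supercritical attenuation maps (Gamma > 1 in places): subcritical sites decay,
supercritical sites grow until the sigmoid saturates, producing spontaneous
oscillations confined to the amplifying domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np

from .activation import phi

__all__ = [
    "SourceSpec",
    "InputSchedule",
    "step",
    "evolve",
    "linear_step",
    "modulated_step",
    "evolve_modulated",
    "AmplitudeAccumulator",
]


@dataclass(frozen=True)
class SourceSpec:
    """A point source injected at a single lattice site.

    ``kind="tone"`` injects ``amplitude * frequency**n`` at ``site`` on step n
    (``frequency`` a unit-modulus complex number, lambda = e^{i theta});
    ``kind="white_noise"`` injects ``amplitude`` times a standard complex
    Gaussian drawn from a generator seeded with ``seed``.
    """

    site: tuple
    kind: str = "tone"
    amplitude: float = 1e-3
    frequency: complex | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("tone", "white_noise"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.kind == "tone":
            if self.frequency is None:
                raise ValueError("tone source requires a frequency")
            if abs(abs(complex(self.frequency)) - 1.0) > 1e-9:
                raise ValueError("tone frequency must have unit modulus")
        if self.kind == "white_noise" and self.seed is None:
            raise ValueError("white_noise source requires a seed")


@dataclass
class InputSchedule:
    """Composite input: constant part + point sources + optional hook.

    The input at step n is ``constant + sum(sources at n) + hook(n)``; the
    hook (if any) returns a full field and is re-evaluated every step.
    Noise sources are reproducible: each ``evolve`` call re-seeds them.
    """

    constant: np.ndarray | float = 0.0
    sources: Sequence[SourceSpec] = dc_field(default_factory=tuple)
    hook: Optional[Callable[[int], np.ndarray]] = None

    def fresh_rngs(self):
        return [
            np.random.default_rng(s.seed) if s.kind == "white_noise" else None
            for s in self.sources
        ]

    def add_to(self, buf: np.ndarray, n: int, rngs) -> None:
        """Add the step-n input into ``buf`` in place."""
        buf += self.constant
        for src, rng in zip(self.sources, rngs):
            site = tuple(np.atleast_1d(src.site).astype(int))
            if src.kind == "tone":
                buf[site] += src.amplitude * complex(src.frequency) ** n
            else:
                buf[site] += src.amplitude * (
                    rng.standard_normal() + 1j * rng.standard_normal()
                )
        if self.hook is not None:
            buf += self.hook(n)


def _check_shapes(a: np.ndarray, b, name: str) -> None:
    shape = getattr(b, "lattice_shape", None) or np.shape(b)
    if shape and tuple(a.shape) != tuple(shape):
        raise ValueError(f"shape mismatch: field {a.shape} vs {name} {shape}")


def step(Z: np.ndarray, U, I) -> np.ndarray:
    """One application of the full map: ``phi(U (x) Z + I)``.

    ``U`` is anything with an ``apply`` method (a :class:`UnitaryKernel` or a
    dense coupling); ``I`` is a field or scalar.
    """
    Z = np.asarray(Z)
    if np.ndim(I) > 0:
        _check_shapes(Z, I, "input")
    return phi(U.apply(Z) + I)


def evolve(
    Z0,
    U,
    schedule: InputSchedule,
    n_steps: int,
    record_every: int | None = None,
    observer: Optional[Callable[[int, np.ndarray], None]] = None,
):
    """Iterate the full map for ``n_steps``.

    Returns ``(snapshots, Z_final)`` where ``snapshots`` is a list of
    ``(step, field)`` pairs taken every ``record_every`` steps (never, if
    None).  Deterministic given the schedule's seeds.  Raises RuntimeError
    with the step index if the state stops being finite.

    ``observer(n, Z)`` (if given) is called after every step; it is the hook
    for running diagnostics without storing trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    Z = np.asarray(Z0, dtype=complex).copy()
    rngs = schedule.fresh_rngs()
    snapshots = []
    for n in range(n_steps):
        buf = U.apply(Z)
        schedule.add_to(buf, n, rngs)
        Z = phi(buf)
        if not np.all(np.isfinite(Z)):
            raise RuntimeError(f"state became non-finite at step {n + 1}")
        if record_every is not None and (n + 1) % record_every == 0:
            snapshots.append((n + 1, Z.copy()))
        if observer is not None:
            observer(n + 1, Z)
    return snapshots, Z


def linear_step(dZ: np.ndarray, Gamma, U, forcing=None) -> np.ndarray:
    """One step of the linearized map: ``Gamma . (U (x) dZ + forcing)``.

    ``Gamma`` is the real attenuation field (or scalar); the forcing (a field,
    or None for free evolution) is attenuated along with the convolved state
    because both enter the argument of phi in the full map.  The map is exactly
    linear in both ``dZ`` and ``forcing``.
    """
    dZ = np.asarray(dZ)
    if np.ndim(Gamma) > 0:
        _check_shapes(dZ, Gamma, "Gamma")
    out = U.apply(dZ)
    if forcing is not None:
        if np.ndim(forcing) > 0:
            _check_shapes(dZ, forcing, "forcing")
        out = out + forcing
    return np.asarray(Gamma) * out


def modulated_step(dZ: np.ndarray, Gamma, U) -> np.ndarray:
    """Saturating slope-modulated step: ``phi(Gamma . (U (x) dZ))``.

    Used for supercritical maps: where Gamma > 1 perturbations grow until the
    sigmoid saturates them; where Gamma < 1 they decay.  Gamma must be > 0.
    """
    dZ = np.asarray(dZ)
    Gamma = np.asarray(Gamma)
    if np.any(Gamma <= 0):
        raise ValueError("Gamma must be > 0")
    if Gamma.ndim > 0:
        _check_shapes(dZ, Gamma, "Gamma")
    return phi(Gamma * U.apply(dZ))


def evolve_modulated(dZ0, Gamma, U, n_steps: int, record_every: int | None = None):
    """Iterate :func:`modulated_step`; same return convention as :func:`evolve`."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dZ = np.asarray(dZ0, dtype=complex).copy()
    snapshots = []
    for n in range(n_steps):
        dZ = modulated_step(dZ, Gamma, U)
        if not np.all(np.isfinite(dZ)):
            raise RuntimeError(f"state became non-finite at step {n + 1}")
        if record_every is not None and (n + 1) % record_every == 0:
            snapshots.append((n + 1, dZ.copy()))
    return snapshots, dZ


class AmplitudeAccumulator:
    """Trailing-window RMS of |Z - reference| per site.

    Feed it states with :meth:`add`; :meth:`rms_map` returns
    sqrt(mean |Z - ref|^2) over everything added so far.  Used as the standard
    "signal amplitude" readout (the mean is over a trailing window of steps,
    default 1024 in the experiment drivers).
    """

    def __init__(self, reference=0.0):
        self.reference = reference
        self._sum = None
        self.count = 0

    def add(self, Z: np.ndarray) -> None:
        d = np.abs(np.asarray(Z) - self.reference) ** 2
        if self._sum is None:
            self._sum = d
        else:
            self._sum += d
        self.count += 1

    def rms_map(self) -> np.ndarray:
        if self.count == 0:
            raise RuntimeError("no states accumulated")
        return np.sqrt(self._sum / self.count)
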