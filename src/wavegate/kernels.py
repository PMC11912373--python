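"""Unitary convolution kernels from anti-Hermitian generators.

A compact kernel A indexed by signed offsets (center at offset 0) is
anti-Hermitian as a convolution operator when A(-x) = -conj(A(x)).  Its
Fourier transform is then purely imaginary -- this is the dispersion relation,
assigning a non-decaying temporal frequency to each spatial wavenumber -- and
its convolutional exponential

    U = exp_conv(A) = F^-1[ exp(F[A]) ]

is unitary: |F[U]| = 1 at every wavenumber, so convolution with U conserves
the L2 norm of the layer.

Conventions
-----------
* Compact kernels have odd side lengths; entry ``kernel[c + x]`` (c the center
  index) is the coupling at signed offset x.  Lattice embedding puts offset 0
  at lattice index 0, so spectra are directly comparable across lattice sizes.
* Wavenumbers are integer DFT frequencies k in [0, N) per axis (numpy.fft
  ordering).
* ``build_circulant_matrix`` materializes the linear-algebra representation
  [k (x)] of convolution in the column-concatenation (Fortran-order) basis;
  it is the package's cross-validation oracle for the FFT path.

Presets
-------
``"ilap3"``  -- i times the finite-difference Laplacian ([1,-2,1] in 1D, the
5-point stencil with center -4 in 2D), the workhorse wave kernel.
``"random7"``-- seeded random complex 7x7 kernel, anti-Hermitized and masked
to a disk of radius 3 (a 7x7 kernel with rounded corners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitaryKernel",
    "anti_hermitize",
    "anti_hermiticity_violation",
    "disk_mask",
    "embed_kernel",
    "conv_exp",
    "build_circulant_matrix",
    "circulant_from_wrapped",
    "unroll",
    "reroll",
    "pick_eigenfrequency",
    "preset_generator",
]


def _check_odd(kernel: np.ndarray) -> None:
    if any(s % 2 == 0 for s in kernel.shape):
        raise ValueError(
            f"kernel shape {kernel.shape} has an even side: no center offset"
        )


def anti_hermitize(raw) -> np.ndarray:
    """Project a compact kernel onto its anti-Hermitian part.

    Returns ``(raw(x) - conj(raw(-x))) / 2``, which satisfies
    ``A(-x) = -conj(A(x))`` exactly.  Kernels that are already anti-Hermitian
    (e.g. i times a real symmetric stencil) pass through unchanged; purely
    real symmetric kernels are annihilated.
    """
    raw = np.asarray(raw, dtype=complex)
    _check_odd(raw)
    flipped = raw[tuple(slice(None, None, -1) for _ in raw.shape)]
    return 0.5 * (raw - np.conj(flipped))


def anti_hermiticity_violation(kernel: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Max |A(x) + conj(A(-x))| over offsets and the offset where it occurs."""
    kernel = np.asarray(kernel, dtype=complex)
    _check_odd(kernel)
    flipped = kernel[tuple(slice(None, None, -1) for _ in kernel.shape)]
    dev = np.abs(kernel + np.conj(flipped))
    idx = np.unravel_index(int(np.argmax(dev)), dev.shape)
    center = tuple(s // 2 for s in kernel.shape)
    offset = tuple(int(i - c) for i, c in zip(idx, center))
    return float(dev[idx]), offset


def disk_mask(kernel, radius: int) -> np.ndarray:
    """Zero all entries at Euclidean offset > ``radius`` from the center."""
    kernel = np.asarray(kernel, dtype=complex).copy()
    _check_odd(kernel)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = tuple(s // 2 for s in kernel.shape)
    grids = np.ogrid[tuple(slice(0, s) for s in kernel.shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    kernel[r2 > radius**2] = 0.0
    return kernel


def embed_kernel(kernel, lattice_shape) -> np.ndarray:
    """Wrap a compact kernel onto a periodic lattice with offset 0 at index 0."""
    kernel = np.asarray(kernel, dtype=complex)
    _check_odd(kernel)
    lattice_shape = tuple(int(s) for s in np.atleast_1d(lattice_shape))
    if len(lattice_shape) != kernel.ndim:
        raise ValueError("lattice dimensionality does not match kernel")
    if any(L < s for L, s in zip(lattice_shape, kernel.shape)):
        raise ValueError("lattice smaller than kernel support")
    emb = np.zeros(lattice_shape, dtype=complex)
    emb[tuple(slice(0, s) for s in kernel.shape)] = kernel
    shift = tuple(-(s // 2) for s in kernel.shape)
    return np.roll(emb, shift, axis=tuple(range(kernel.ndim)))


@dataclass(frozen=True)
class UnitaryKernel:
    """A unitary convolution kernel U = exp_conv(A) with cached spectrum.

    Attributes
    ----------
    generator : ndarray
        The compact anti-Hermitian generator A (odd side lengths).
    lattice_shape : tuple of int
        Periodic lattice the kernel acts on.
    spectrum : ndarray
        F[U] = exp(F[A]) on the full lattice; unit modulus everywhere.  Its
        entries are the eigenvalues of the convolution, indexed by wavenumber.
    """

    generator: np.ndarray
    lattice_shape: tuple
    spectrum: np.ndarray = field(repr=False)

    @property
    def ndim(self) -> int:
        return len(self.lattice_shape)

    @property
    def support_radius(self) -> int:
        return max(s // 2 for s in self.generator.shape)

    def apply(self, Z: np.ndarray) -> np.ndarray:
        """Convolve: U (x) Z via spectrum multiplication in Fourier space."""
        Z = np.asarray(Z)
        if Z.shape != self.lattice_shape:
            raise ValueError(
                f"field shape {Z.shape} does not match lattice {self.lattice_shape}"
            )
        return np.fft.ifftn(self.spectrum * np.fft.fftn(Z))

    def realspace(self) -> np.ndarray:
        """The wrapped real-space kernel U (full lattice, offset 0 at index 0)."""
        return np.fft.ifftn(self.spectrum)


def conv_exp(A, lattice_shape, tol: float = 1e-12) -> UnitaryKernel:
    """Exponentiate an anti-Hermitian compact kernel into a unitary one.

    Computes F[A] on the periodic lattice and returns the kernel with spectrum
    exp(F[A]).  Anti-Hermiticity of A is verified first (to ``tol`` relative
    to the largest entry); violation raises with the offending offset.
    """
    A = np.asarray(A, dtype=complex)
    dev, offset = anti_hermiticity_violation(A)
    scale = max(float(np.abs(A).max()), 1.0)
    if dev > tol * scale:
        raise ValueError(
            f"generator is not anti-Hermitian: |A(x)+conj(A(-x))| = {dev:.3g}"
            f" at offset {offset}"
        )
    emb = embed_kernel(A, lattice_shape)
    FA = np.fft.fftn(emb)
    # F[A] is purely imaginary for an anti-Hermitian kernel; discard the
    # roundoff real part so |F[U]| = 1 holds to machine precision.
    spectrum = np.exp(1j * FA.imag)
    return UnitaryKernel(generator=A, lattice_shape=emb.shape, spectrum=spectrum)


def unroll(Z: np.ndarray) -> np.ndarray:
    """Flatten a field to a vector in the column-concatenation basis."""
    return np.asarray(Z).ravel(order="F")


def reroll(v: np.ndarray, lattice_shape) -> np.ndarray:
    """Inverse of :func:`unroll`."""
    return np.asarray(v).reshape(tuple(lattice_shape), order="F")


_CIRCULANT_SITE_GUARD = 4096


def circulant_from_wrapped(wrapped: np.ndarray) -> np.ndarray:
    """Dense matrix [k (x)] of convolution with a wrapped (full-lattice) kernel.

    In the column-concatenation basis: ``M @ unroll(Z) == unroll(k (x) Z)``.
    Guarded to lattices of at most 4096 sites.
    """
    wrapped = np.asarray(wrapped, dtype=complex)
    n_sites = wrapped.size
    if n_sites > _CIRCULANT_SITE_GUARD:
        raise ValueError(
            f"lattice has {n_sites} sites; circulant materialization is guarded"
            f" to {_CIRCULANT_SITE_GUARD}"
        )
    shape = np.array(wrapped.shape)
    coords = np.stack(
        [g.ravel(order="F") for g in np.indices(wrapped.shape)]
    )  # (ndim, n_sites)
    diff = (coords[:, :, None] - coords[:, None, :]) % shape[:, None, None]
    return wrapped[tuple(diff)]


def build_circulant_matrix(kernel, lattice_shape) -> np.ndarray:
    """Dense [k (x)] for a compact kernel on a periodic lattice (oracle path)."""
    return circulant_from_wrapped(embed_kernel(kernel, lattice_shape))


def pick_eigenfrequency(U: UnitaryKernel, wavenumber) -> complex:
    """Eigenvalue of the convolution at an integer wavenumber.

    Wavenumbers follow DFT ordering, k in [0, N) per axis.  The returned
    value lies on the unit circle.
    """
    k = tuple(int(x) for x in np.atleast_1d(wavenumber))
    if len(k) != U.ndim:
        raise ValueError(f"wavenumber {k} has wrong dimensionality for {U.lattice_shape}")
    for ki, Ni in zip(k, U.lattice_shape):
        if not (0 <= ki < Ni):
            raise ValueError(f"wavenumber {k} out of range for lattice {U.lattice_shape}")
    return complex(U.spectrum[k])


def preset_generator(name: str, ndim: int = 2, seed: int = 0) -> np.ndarray:
    """Named compact anti-Hermitian generators.

    ``"ilap3"``: i times the unscaled finite-difference Laplacian stencil
    ([1,-2,1] in 1D; 5-point, center -4, in 2D).
    ``"random7"``: seeded complex Gaussian 7x7 (2D only), anti-Hermitized and
    disk-masked to radius 3.
    """
    if name == "ilap3":
        if ndim == 1:
            return 1j * np.array([1.0, -2.0, 1.0])
        if ndim == 2:
            return 1j * np.array(
                [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
            )
        raise ValueError("ilap3 defined for 1D and 2D only")
    if name == "random7":
        if ndim != 2:
            raise ValueError("random7 is a 2D preset")
        rng = np.random.default_rng(seed)
        raw = rng.standard_normal((7, 7)) + 1j * rng.standard_normal((7, 7))
        return disk_mask(anti_hermitize(raw), radius=3)
    raise ValueError(f"unknown kernel preset {name!r}")
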