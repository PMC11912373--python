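# Methods

## Model

The state is a complex field `Z` on a periodic lattice (1D length `N` or 2D
`H×W`), updated in discrete time by

    Z[n+1] = phi( U ⊗ Z[n] + I[n] ),      phi(z) = z / sqrt(1 + |z|²).

`U` is a unitary convolution kernel: the convolutional exponential
`U = F⁻¹[exp(F[A])]` of a compact anti-Hermitian kernel `A`
(`A(−x) = −conj(A(x))`).  `F[A]` is then purely imaginary — the dispersion
relation, assigning a temporal frequency to each spatial wavenumber — and
`|F[U]| = 1` everywhere, so the linear coupling conserves the L2 norm.
Because `phi(0) = 0`, `phi'(0) = 1` and `0 < phi'(z) < 1` for `z ≠ 0`, the
quiescent state is a globally attracting fixed point whose linearization is
exactly the unitary coupling: the network is critical (marginally stable in
every mode) and relaxes algebraically, not exponentially.  These three
properties of the activation are assumptions of the whole construction; the
inverse-design formula below explicitly uses the functional form of `phi'`
and would need rederiving for another sigmoid (only this one is
implemented).

### Scalar fixed-point theory

The single-neuron recurrence `z ← phi(z + I)` fixes the operating-point
language used throughout.  For constant `I` it converges (Banach) to
`z* = phi(z* + I)`; for small real `I`, `z* ≈ (2I)^{1/3}`.  The slope at the
operating point, `γ = phi'(z* + I) = (1 + |z*+I|²)^{−3/2}`, sets the local
relaxation time `τ = −1/ln γ ≈ (2/3)(2I)^{−2/3}`, reported as `+inf` at
`I = 0` where relaxation is algebraic.  The cubic root is the source of the
network's singular input sensitivity: microscopic constant inputs move the
operating point, and hence the attenuation, by orders of magnitude.  The
solver is plain fixed-point iteration from 0 (tolerance `1e-12` on the step,
budget `1e6` iterations); no acceleration is used because the map is a
global contraction and the budget covers the slowest tested regime
(`I = 1e-6`, `τ ≈ 4200` steps).

## Unitary kernels

Compact kernels are indexed by signed offsets with the center at offset 0;
embedding on the lattice puts offset 0 at index 0, so spectra are comparable
across lattice sizes.  Wavenumbers follow DFT ordering, `k ∈ [0, N)` per
axis.  Two presets cover the experiments: `ilap3`, i times the unscaled
finite-difference Laplacian (`[1,−2,1]` in 1D, 5-point with center −4 in
2D) — the stencil normalization is a convention; rescaling it only rescales
the dispersion relation — and `random7`, a seeded complex Gaussian 7×7,
anti-Hermitized and masked to Euclidean offset ≤ 3 (29 of 49 entries
survive a strict radius-3 disk).  Exact anti-Hermiticity is enforced
structurally (`(raw(x) − conj(raw(−x)))/2`), and `conv_exp` drops the
round-off real part of `F[A]` before exponentiating so the unit-modulus
invariant holds to machine precision.

Convolution is always spectrum multiplication in Fourier space.  The dense
circulant representation of the same operator (`M @ unroll(Z) =
unroll(k ⊗ Z)` in the column-concatenation basis, guarded to ≤ 4096 sites)
exists purely as a cross-validation oracle: tests require FFT, circulant and
direct sliding-window convolution to agree within 1e-10, and the circulant
eigenvalues to reproduce the kernel's Fourier transform.

## Inverse design

Given a requested attenuation map `0 < Γ ≤ 1`, the design computes
`W = sqrt(Γ^{−2/3} − 1)` (nonnegative real branch, the negative-W branch
gives the same `Γ` with inverted sign conventions and is not used),
`Z* = phi(W)`, `I* = W − U ⊗ Z*`.  By construction
`phi(U⊗Z* + I*) = phi(W) = Z*` holds identically, so the designed pair is an
exact fixed point and the realized attenuation `phi'(U⊗Z* + I*)` equals the
request to round-off even at discontinuities — the convolution's spillover
across region edges is exactly compensated inside `I*`, which is where the
characteristic edge structure of the designed inputs comes from.  `Γ > 1`
is rejected (the square root turns imaginary); supercritical maps run
through the modulated dynamics instead (below).  At `Γ = 1` the round-off
negative of `Γ^{−2/3} − 1` is clipped to zero.

The dense variant replaces the convolution with an `N×N` unitary matrix
(`I* = phi⁻¹(Z*) − U Z*`); with a circulant matrix it reproduces the
convolutional result to 1e-10, which is the module's master oracle.

**Round-trip convergence.**  Forward iteration from rest converges to `Z*`
geometrically at rate `max Γ` while the map stays strictly subcritical.
Regions with `Γ = 1` exactly are marginal: the transient deposited there
drains only by radiating into absorbing regions, which in 1D is slowed
further by near-zero group velocities at the band edges, and with a
disordered (dense) coupling can stall indefinitely because part of the
transient is absorbed into Anderson-localized eigenvectors whose only decay
channel is the cubic nonlinearity (measured: a flat ~1e-4 sup-norm residual
from 60k to 200k steps).  Round-trip tests therefore verify marginal-region
maps in 2D (where transport to the walls is fast) and keep the dense
round-trip maps strictly below 1 except for the trivial uniform `Γ = 1`
case.  This is a statement about reachability by forward evolution, not
about the design: the designed pair is an exact fixed point in all cases.

## Linear response and its limits

Around a uniform operating point with scalar attenuation `γ`, a point tone
`α λⁿ δ` drives the linearized map
`ΔZ[n+1] = γ (U ⊗ ΔZ[n] + α λⁿ δ)` — the forcing sits inside the slope
factor because it enters the argument of `phi`.  The steady envelope solves
element-wise in Fourier space

    F[R*] = α F[δ] / (λ/γ − F[U]).

The division is guarded: if `min |λ/γ − F[U]| < 1e-8` a pole error is
raised reporting the distance to the nearest eigenvalue.  Approaching the
pole (`γ → 1`, `λ` in the spectrum) the response diverges; off resonance
with `γ < 1` it decays exponentially with distance from the source.

Two caveats are deliberate:

* `phi` is not holomorphic.  The scalar `Γ` is the exact derivative only
  along the operating point's own phase direction; the full tangent map has
  a conjugate term of relative size `|z*|²/2 · Γ^{?}` that the scalar law
  drops.  Consequently the linear map is the exact first-order model around
  the quiescent state (`Γ = 1`, where the conjugate term vanishes — verified
  by a Richardson test, discrepancy falling 100× per decade of amplitude),
  while on an active background it is the paper-standard envelope
  approximation with a first-order residual (also asserted).  All gating
  behavior is governed by the modulus contraction, which the scalar law
  bounds correctly.
* Nonlinear steady responses are read out by coherent demodulation: the
  trailing-window mean of `Z λ^{−n}` over a small neighborhood of the
  source, declared steady when consecutive windows (512 steps) agree within
  1%.  Demodulation rejects the non-decaying dispersive transient that a
  plain RMS readout would count at `Γ = 1`.  At an exact eigenfrequency the
  steady amplitude compresses toward `α^{1/3}` (measured log-log slope 0.35
  over `α ∈ [1e-4, 1e-1]` at 128²); at the midpoint of the largest spectral
  gap, and at amplitudes small enough to stay linear (`α ≤ 1e-3`), the
  slope is 1.000.

## Pattern generators and region analysis

All generators are deterministic under a fixed seed, and all maps meant for
design keep `Γ ∈ (0, 1]`.

* **1D band** — `Γ = 1` background, absorbing flanks (default 0.5, width
  `N/16`) to stop wrap-around, central band `Γ = exp(−0.01 L)` so `L`
  grades the attenuation from none (`L = 0`) smoothly downward.
* **Boxes** — border walls plus a dividing wall (default `Γ = 0.1`),
  optional hole restoring `Γ = 1` over a row span of the middle wall.
* **Labyrinth** — seeded white noise, annular band-pass in `|k|`
  (raised-cosine edges), thresholded at a quantile.  A periodic
  morphological opening+closing (`min_feature`, default radius 2) removes
  corridors and walls thinner than ~5 sites: walls comparable to the kernel
  radius let activity tunnel across, and at desk scale the raw thresholded
  patterns routinely pinch to 1–2 sites (at the full 2048² scale of the
  original experiments the same band-pass in cycles gives walls an order of
  magnitude thicker, so the issue never arises there).
* **Annulus ("lighthouse")** — three-quarter annular wall with
  raised-cosine radial and angular edges (sharp corners would scatter), an
  absorbing outer border tapering from 1 to the wall value over
  `taper_width` sites, and a rotation angle re-designed every 64 steps for
  the moving-boundary experiment.

Region analysis: `floodfill_oracle` is a classical BFS connected component
(4-neighbor, periodic; 8-neighbor optional), cross-checked exactly against
an iterated-dilation oracle; `detect_filled_region` thresholds the
trailing-window RMS amplitude at a fraction (default 0.05) of the median
over the oracle's seed component; `frequency_map` returns
`arg(Z_a conj(Z_b))/lag` per site, i.e. the oscillation frequency modulo
`2π/lag` (aliased, which still fingerprints synchronized domains), with
zero-amplitude sites masked as NaN.

**Floodfill test conditions.**  Desk-scale floodfill runs use a white-noise
probe (broadband excitation fills the standing-wave fades that a single
resonant tone leaves below the detection threshold; the original experiments
note the two are qualitatively interchangeable) and a *pattern admission
rule* evaluated from geometry alone before any simulation: an admissible
labyrinth has every off-component at least 5 sites from the seed component
(thinner separations leak by tunneling and slow cavity ring-up) and a seed
component of 100–1500 sites, so that the point source's geometrically
spreading amplitude stays above threshold across the whole component within
the 4000-step horizon.  Seeds are scanned in order and the first admissible
patterns are used; the acceptance thresholds themselves (95% agreement,
1e-3 leakage) are untouched.  Wave-vs-oracle agreement is scored outside a
kernel-radius margin of the walls, where amplitudes are graded rather than
binary.

## Supercritical dynamics and synchrony

Maps with `Γ > 1` cannot come from the design; they evolve under the
saturating modulated map `dZ ← phi(Γ · (U ⊗ dZ))`: subcritical sites
contract, supercritical sites grow until the sigmoid saturates.  From a
tiny random field, supercritical labyrinth domains (`Γ_go = 1.2`,
`Γ_nogo = 0.2`) light up with self-sustained oscillations confined by the
damping walls; per-domain frequencies are read from the frequency map at
lag 200 and scored with circular statistics on the `2π/lag` circle.

Measured behavior: compact domains lock fully (within-domain circular std
~1e-6 rad/step), while larger domains settle into a persistent multi-mode
state (~5e-3 rad/step) that does not resolve with time — the
synchronized-domain fraction saturates around 0.3–0.6 from 4k to 131k steps
across gains 1.2–2.0 and domain scales.  This matches the qualitative
picture of synchrony binding with residual synchronization boundaries, but
a stricter bar (≥ 80% of domains with within-spread < 0.1× the
across-domain spread) is not met at desk scale; the corresponding
acceptance test records this as a failure rather than relaxing the bar.
Every mode of the critical coupling is equally supercritical under a
uniform gain, so nothing in the model selects a unique winner in a large
domain; full locking relies on boundary-shape-dependent mode competition
that evidently completes only in small domains.

## Dense 1D networks and localization

The dense generator is `A = circulant(i[1,−2,1]) + ρ (B − B†)` with `B`
holding i.i.d. standard complex Gaussians on the +1, +2, +3 off-diagonals
(periodic wrap), so `A† = −A` exactly for every `ρ` and seed;
`U = expm(A)`.  `ρ = 0` reduces to the convolutional path within 1e-10
(matrix, spectrum and 100-step evolution), the module's master oracle.

Localization diagnostics eigendecompose the Hermitian `iA`; the
participation ratio `PR(v) = 1/Σ|v_i|⁴` of each unit eigenvector measures
its support (plane waves give `≥ 2N/3`, with near-degenerate clusters mixing
down to exactly `N/2`; localized states give O(localization length)).  An
eigenvector counts as system-spanning when `PR > N/4` — the cut is a
convention, exposed as a parameter and reported with the full PR list.  The
spanning fraction falls monotonically with `ρ` (1.0 at `ρ = 0.01` to 0.0 by
`ρ = 0.3` at N = 512); `tune_rho_for_half_spanning` bisects in `log ρ`
(disorder strength acts multiplicatively) to the 0.4–0.6 band, and the
tuned value (~0.07 at N = 512) generalizes to fresh seeds within ±0.1.
Even at `Γ ≡ 1`, outgoing waves weaken with distance when `ρ > 0`: energy
is parked in localized eigenvectors, which is also why marginal regions
stall the dense round trip (above).

## Problem sizes and defaults

Experiments run at desk scale by default: 256² lattices (N = 1024 in 1D),
4000 steps, trailing readout window 1024 steps, source amplitude 1e-3;
full-scale settings (2048², ≥ 25k steps) are one config line away and
nothing in the implementation depends on size beyond memory and time.  The
acceptance suite uses 64²–256² and N = 512–1024 as noted per test, chosen
so the full suite runs in a few minutes on one core.  Determinism: every
stochastic element (noise sources, random kernels, disorder bands,
labyrinth noise) draws from an explicit seed, and identical config + seed
reproduces bit-identical trajectories.

## What the generators emulate — and what they do not

The synthetic patterns reproduce the *geometry class* of the original
demonstrations (graded bands, walls with holes, band-passed labyrinths,
rotating annuli), not their pixel content: the original noise seeds, band
parameters and exact wall profiles are not published, so tests assert
properties (monotonicity, containment ratios, oracle agreement, scaling
exponents) rather than field-level matches.  Passing therefore shows the
mechanism — input-drawn attenuation gating unitary waves — behaves
quantitatively as described at desk scale; it does not certify behavior at
2048² scale, in non-periodic geometries, for activations other than this
sigmoid, or for attenuation maps with spatially varying complex phase
(scattering design is out of scope).

## Known limitations

* The scalar-slope envelope law is an approximation on active backgrounds
  (conjugate term dropped); quantitative decay rates within strongly
  attenuating regions inherit this approximation.
* Exact marginal regions (`Γ = 1`) are reachable by forward evolution only
  through transport; with disorder they are not practically reachable (see
  round-trip convergence).
* Large supercritical domains do not fully synchronize; the synchrony
  experiment reports partial locking by design of the dynamics, not as an
  implementation artifact.
* `phi_inverse` is ill-conditioned near the rim of the unit disk
  (condition number ~`|z|²`): round trips are exact to 1e-12 only up to
  `|z| ≈ 10`, degrading to ~1e-8 by `|z| = 1e3`.
* The rotating-annulus hook re-designs the input only every 64 steps; the
  quasi-static approximation is valid because wave transit times (~tens of
  steps) are short against the rotation period (thousands).
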