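"""Attenuation-map generators and region analysis utilities.

Generators for the canonical gating geometries:

* a 1D two-box layout with absorbing flanks and a graded central band,
* 2D side-by-side boxes with strongly attenuating walls and an optional hole,
* seeded labyrinths from thresholded band-passed noise (go / no-go regions),
* a rotating three-quarter annulus with raised-cosine tapers ("lighthouse").

Analysis utilities: a classical BFS floodfill (the connectedness oracle the
wave dynamics is compared against), amplitude-based region detection, and
per-site oscillation-frequency maps from two snapshots.

All generators are deterministic under a fixed seed, and all maps meant for
inverse design keep Gamma in (0, 1].
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionPattern",
    "BoxesPattern",
    "make_band_1d",
    "make_boxes_2d",
    "make_labyrinth",
    "make_annulus",
    "floodfill_oracle",
    "dilation_fill",
    "detect_filled_region",
    "frequency_map",
    "interior_mask",
    "periodic_label",
]


@dataclass(frozen=True)
class RegionPattern:
    """A boolean go / no-go patterning of the lattice.

    ``to_gamma`` maps it to an attenuation array (go -> gamma_go,
    complement -> gamma_nogo).  gamma_go may exceed 1 for supercritical
    (spontaneously oscillating) experiments; such maps must be run through
    the modulated dynamics, not the inverse design.
    """

    go: np.ndarray
    gamma_go: float = 1.0
    gamma_nogo: float = 0.01

    def to_gamma(self, gamma_go: float | None = None, gamma_nogo: float | None = None):
        g_go = self.gamma_go if gamma_go is None else gamma_go
        g_nogo = self.gamma_nogo if gamma_nogo is None else gamma_nogo
        return np.where(self.go, g_go, g_nogo)


@dataclass(frozen=True)
class BoxesPattern:
    """Two side-by-side boxes: attenuation array plus interior region masks."""

    gamma: np.ndarray
    left_box: np.ndarray
    right_box: np.ndarray
    wall: np.ndarray


def make_band_1d(
    N: int,
    flank_value: float = 0.5,
    band_range: tuple | None = None,
    band_L: float = 0,
    flank_width: int | None = None,
) -> np.ndarray:
    """1D map: Gamma = 1 with absorbing flanks and a central graded band.

    The flanks (width ``flank_width``, default N//16, at each end) are set to
    ``flank_value`` to stop waves wrapping around; the band (``band_range``
    half-open slice, default the central quarter) is set to exp(-0.01 * L),
    so L = 0 means no attenuation and larger L a deeper band.
    """
    if flank_width is None:
        flank_width = N // 16
    if band_range is None:
        band_range = (N // 2 - N // 8, N // 2 + N // 8)
    lo, hi = int(band_range[0]), int(band_range[1])
    if not (0 <= lo < hi <= N):
        raise ValueError(f"band range {band_range} outside lattice of length {N}")
    if lo < flank_width or hi > N - flank_width:
        raise ValueError("band overlaps the absorbing flanks")
    gamma = np.ones(N)
    gamma[:flank_width] = flank_value
    gamma[N - flank_width:] = flank_value
    gamma[lo:hi] = np.exp(-0.01 * float(band_L))
    return gamma


def make_boxes_2d(
    shape: tuple,
    wall_gamma: float = 0.1,
    hole: tuple | None = None,
    wall_thickness: int | None = None,
) -> BoxesPattern:
    """Two boxes side by side separated by a strongly attenuating wall.

    A border wall runs around the whole lattice and a vertical middle wall
    splits it into a left and a right box (interiors Gamma = 1).  ``hole``,
    if given, is a half-open row span (r0, r1) on the middle wall where
    Gamma = 1 is restored, opening a channel between the boxes.
    """
    H, W = (int(s) for s in shape)
    t = wall_thickness if wall_thickness is not None else max(2, min(H, W) // 16)
    if t < 1:
        raise ValueError("wall thickness must be >= 1")
    wall = np.zeros((H, W), dtype=bool)
    wall[:t, :] = wall[-t:, :] = True
    wall[:, :t] = wall[:, -t:] = True
    mid_lo = W // 2 - t // 2
    mid_hi = mid_lo + t
    wall[:, mid_lo:mid_hi] = True
    if hole is not None:
        r0, r1 = int(hole[0]), int(hole[1])
        if not (t <= r0 < r1 <= H - t):
            raise ValueError(
                f"hole rows {hole} fall outside the middle wall interior"
                f" (rows {t}..{H - t})"
            )
        wall[r0:r1, mid_lo:mid_hi] = False
    gamma = np.where(wall, float(wall_gamma), 1.0)
    left = np.zeros_like(wall)
    left[t:H - t, t:mid_lo] = True
    right = np.zeros_like(wall)
    right[t:H - t, mid_hi:W - t] = True
    if hole is not None:
        left &= ~wall
        right &= ~wall
    return BoxesPattern(gamma=gamma, left_box=left, right_box=right, wall=wall)


def _radial_bandpass_weight(shape, band_low, band_high):
    freqs = [np.fft.fftfreq(n, d=1.0 / n) for n in shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    w = np.zeros(shape)
    edge = 0.25 * (band_high - band_low)
    core_lo, core_hi = band_low + edge, band_high - edge
    w[(r >= core_lo) & (r <= core_hi)] = 1.0
    rise = (r >= band_low) & (r < core_lo)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (r[rise] - band_low) / edge))
    fall = (r > core_hi) & (r <= band_high)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (r[fall] - core_hi) / edge))
    return w


def _square_dilate(mask: np.ndarray, r: int) -> np.ndarray:
    out = mask.copy()
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy or dx:
                out |= np.roll(mask, (dy, dx), axis=(0, 1))
    return out


def _regularize(go: np.ndarray, r: int) -> np.ndarray:
    # periodic morphological opening then closing with a (2r+1)^2 element:
    # removes go features and walls thinner than the element
    opened = _square_dilate(~_square_dilate(~go, r), r)
    return ~_square_dilate(~_square_dilate(opened, r), r)


def make_labyrinth(
    shape: tuple,
    band_low: float = 4.0,
    band_high: float = 10.0,
    threshold_quantile: float = 0.5,
    seed: int = 0,
    gamma_go: float = 1.0,
    gamma_nogo: float = 0.01,
    min_feature: int = 1,
) -> RegionPattern:
    """Labyrinthine go / no-go pattern from thresholded band-passed noise.

    Seeded Gaussian white noise is filtered through an annular band in |k|
    (``band_low``..``band_high`` in cycles across the lattice, raised-cosine
    edges) and thresholded at ``threshold_quantile``: sites above the quantile
    are "go".  The band sets the corridor scale: roughly N / band cycles sites.

    ``min_feature`` (periodic morphological opening + closing radius, 0 to
    disable) removes corridors and walls thinner than ``2*min_feature + 1``
    sites.  Walls approaching the kernel radius let activity tunnel across,
    so desk-scale patterns need this smoothing to keep nominally separate
    regions genuinely separate.
    """
    shape = tuple(int(s) for s in np.atleast_1d(shape))
    nyq = min(shape) / 2
    if not (0 < band_low < band_high < nyq):
        raise ValueError(f"band ({band_low}, {band_high}) must sit inside (0, {nyq})")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    w = _radial_bandpass_weight(shape, band_low, band_high)
    fieldv = np.real(np.fft.ifftn(w * np.fft.fftn(noise)))
    thr = np.quantile(fieldv, threshold_quantile)
    go = fieldv > thr
    if min_feature > 0 and go.ndim == 2:
        go = _regularize(go, int(min_feature))
    if not go.any():
        raise ValueError("empty go region: threshold too high")
    return RegionPattern(go=go, gamma_go=gamma_go, gamma_nogo=gamma_nogo)


def make_annulus(
    shape: tuple,
    radii: tuple = None,
    wall_gamma: float = 0.1,
    rotation_angle: float = 0.0,
    taper_width: int = 8,
    border_gamma: float | None = None,
) -> np.ndarray:
    """Three-quarter annulus wall with tapered absorbing outer border.

    An annular wall (inner/outer ``radii`` around the lattice center, default
    scaled to the lattice) with one quarter turn deleted, the gap centered at
    ``rotation_angle``; both its radial and angular edges are smoothed with
    raised cosines so the wall emits no scatter from sharp corners.  The
    lattice border absorbs outgoing waves through a raised-cosine taper from
    Gamma = 1 down to ``border_gamma`` (default ``wall_gamma``) over
    ``taper_width`` sites; the taper endpoints are exactly 1 and the wall
    value.
    """
    H, W = (int(s) for s in shape)
    if radii is None:
        radii = (min(H, W) / 8.0, min(H, W) / 8.0 + max(3.0, min(H, W) / 32.0))
    r_in, r_out = float(radii[0]), float(radii[1])
    if not (0 < r_in < r_out < min(H, W) / 2):
        raise ValueError(f"radii {radii} do not fit the lattice")
    if border_gamma is None:
        border_gamma = wall_gamma

    yy, xx = np.indices((H, W))
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    # radial wall profile: raised-cosine shoulders over ~1/4 of the wall width
    tw = max((r_out - r_in) / 4.0, 1.0)
    radial = np.zeros((H, W))
    inside = (r >= r_in + tw) & (r <= r_out - tw)
    radial[inside] = 1.0
    up = (r >= r_in) & (r < r_in + tw)
    radial[up] = 0.5 * (1 - np.cos(np.pi * (r[up] - r_in) / tw))
    dn = (r > r_out - tw) & (r <= r_out)
    radial[dn] = 0.5 * (1 + np.cos(np.pi * (r[dn] - (r_out - tw)) / tw))

    # angular gap: one quarter turn centered on rotation_angle, cosine edges
    dtheta = np.angle(np.exp(1j * (theta - rotation_angle)))  # wrapped to (-pi, pi]
    half_gap = np.pi / 4.0
    aw = np.pi / 16.0  # angular smoothing width
    angular = np.ones((H, W))  # 1 = wall present
    in_gap = np.abs(dtheta) <= half_gap - aw
    angular[in_gap] = 0.0
    edge = (np.abs(dtheta) > half_gap - aw) & (np.abs(dtheta) < half_gap + aw)
    angular[edge] = 0.5 * (
        1 - np.cos(np.pi * (np.abs(dtheta[edge]) - (half_gap - aw)) / (2 * aw))
    )

    wallness = radial * angular
    gamma = 1.0 + (float(wall_gamma) - 1.0) * wallness

    # absorbing border taper
    d_edge = np.minimum.reduce([yy, xx, H - 1 - yy, W - 1 - xx]).astype(float)
    border = np.ones((H, W))
    tb = d_edge < taper_width
    border[tb] = float(border_gamma) + (1.0 - float(border_gamma)) * 0.5 * (
        1 - np.cos(np.pi * d_edge[tb] / taper_width)
    )
    return np.minimum(gamma, border)


_NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
_NEIGHBORS_8 = _NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def floodfill_oracle(go_mask, seed_site, connectivity: int = 4) -> np.ndarray:
    """Classical BFS floodfill: connected component of ``seed_site`` in the go
    region, 4-connectivity (8 optional) with periodic wrap.

    This is the package's independent connectedness oracle — the reference the
    wave-filled region is judged against.
    """
    go = np.asarray(go_mask, dtype=bool)
    if go.ndim != 2:
        raise ValueError("floodfill oracle expects a 2D mask")
    seed_site = tuple(int(x) % s for x, s in zip(np.atleast_1d(seed_site), go.shape))
    if not go[seed_site]:
        raise ValueError(f"seed site {seed_site} lies in the no-go region")
    neigh = _NEIGHBORS_4 if connectivity == 4 else _NEIGHBORS_8
    H, W = go.shape
    reached = np.zeros_like(go)
    reached[seed_site] = True
    q = deque([seed_site])
    while q:
        y, x = q.popleft()
        for dy, dx in neigh:
            p = ((y + dy) % H, (x + dx) % W)
            if go[p] and not reached[p]:
                reached[p] = True
                q.append(p)
    return reached


def dilation_fill(go_mask, seed_site, connectivity: int = 4) -> np.ndarray:
    """Morphological alternative to :func:`floodfill_oracle`: iterated
    periodic dilation masked by the go region, to convergence."""
    go = np.asarray(go_mask, dtype=bool)
    seed_site = tuple(int(x) % s for x, s in zip(np.atleast_1d(seed_site), go.shape))
    if not go[seed_site]:
        raise ValueError(f"seed site {seed_site} lies in the no-go region")
    neigh = _NEIGHBORS_4 if connectivity == 4 else _NEIGHBORS_8
    reached = np.zeros_like(go)
    reached[seed_site] = True
    while True:
        grown = reached.copy()
        for dy, dx in neigh:
            grown |= np.roll(reached, (dy, dx), axis=(0, 1))
        grown &= go
        if (grown == reached).all():
            return reached
        reached = grown


def interior_mask(mask, margin: int, connectivity: int = 4) -> np.ndarray:
    """Sites of ``mask`` farther than ``margin`` from its complement
    (periodic).  Used to exclude a wall-adjacent band from scoring, since
    waves penetrate walls over about one attenuation length."""
    mask = np.asarray(mask, dtype=bool)
    comp = ~mask
    neigh = _NEIGHBORS_4 if connectivity == 4 else _NEIGHBORS_8
    for _ in range(int(margin)):
        grown = comp.copy()
        for dy, dx in neigh:
            grown |= np.roll(comp, (dy, dx), axis=(0, 1))
        comp = grown
    return mask & ~comp


def periodic_label(mask, connectivity: int = 4) -> tuple[np.ndarray, int]:
    """Connected-component labeling with periodic wrap.

    Returns (labels, n_components); labels are 1..n on ``mask`` sites and 0
    elsewhere.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    for site in zip(*np.nonzero(mask)):
        if labels[site] == 0:
            n += 1
            comp = floodfill_oracle(mask, site, connectivity=connectivity)
            labels[comp] = n
    return labels, n


def detect_filled_region(amplitude, threshold_rel: float, reference_mask) -> np.ndarray:
    """Sites whose trailing-window RMS amplitude exceeds ``threshold_rel``
    times the median amplitude over ``reference_mask`` (the floodfill oracle's
    seed component)."""
    amplitude = np.asarray(amplitude, dtype=float)
    if not (0 < threshold_rel < 1):
        raise ValueError("threshold_rel must be in (0, 1)")
    if not np.any(amplitude > 0):
        raise ValueError("all-zero amplitude field")
    med = float(np.median(amplitude[np.asarray(reference_mask, dtype=bool)]))
    return amplitude > threshold_rel * med


def frequency_map(Z_a, Z_b, lag: int = 200) -> np.ndarray:
    """Per-site oscillation frequency from two snapshots ``lag`` steps apart.

    Returns arg(Z_a conj(Z_b)) / lag, in (-pi/lag, pi/lag] — the frequency
    modulo 2*pi/lag (frequencies above the lag Nyquist alias, which still
    fingerprints synchronized domains).  Sites where either snapshot vanishes
    are undefined and returned as NaN.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    Z_a = np.asarray(Z_a)
    Z_b = np.asarray(Z_b)
    prod = Z_a * np.conj(Z_b)
    out = np.angle(prod) / lag
    out = np.where(prod == 0, np.nan, out)
    return out
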