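"""Full map, linearized map and modulated (supercritical) map dynamics."""

import numpy as np
import pytest
from scipy import stats

import wavegate as wg
from wavegate import InputSchedule, SourceSpec, evolve, linear_step, modulated_step, step

from conftest import random_field


def test_origin_is_fixed_point(ilap3_2d_64):
    Z = np.zeros((64, 64), complex)
    assert np.all(step(Z, ilap3_2d_64, 0.0) == 0)


def test_shape_mismatch_rejected(ilap3_2d_64):
    with pytest.raises(ValueError, match="mismatch"):
        step(np.zeros((64, 64), complex), ilap3_2d_64, np.zeros((32, 32)))
    with pytest.raises(ValueError):
        ilap3_2d_64.apply(np.zeros((32, 32)))


def test_free_decay_norm_monotone(ilap3_2d_64):
    """With zero input the quiescent state is globally attracting: the norm
    never increases."""
    Z = random_field((64, 64), seed=2)
    norms = [np.linalg.norm(Z)]
    for _ in range(500):
        Z = step(Z, ilap3_2d_64, 0.0)
        norms.append(np.linalg.norm(Z))
    diffs = np.diff(norms)
    assert np.all(diffs <= 1e-14)
    assert norms[-1] < norms[0]


def test_free_decay_is_algebraic_not_exponential(ilap3_2d_64):
    """The fitted exponential rate over successive windows falls toward zero:
    decay at the critical point is slower than any exponential."""
    Z = random_field((64, 64), seed=3)
    norms = []
    for _ in range(1200):
        Z = step(Z, ilap3_2d_64, 0.0)
        norms.append(np.linalg.norm(Z))
    logn = np.log(norms)
    t = np.arange(len(norms))
    rates = [
        -stats.linregress(t[a:b], logn[a:b]).slope
        for a, b in [(0, 200), (500, 700), (1000, 1200)]
    ]
    assert rates[0] > rates[1] > rates[2] > 0
    assert rates[2] < 0.2 * rates[0]


def test_uniform_input_reaches_scalar_fixed_point(ilap3_2d_64):
    I = 0.01
    schedule = InputSchedule(constant=np.full((64, 64), I, dtype=complex))
    _, Z = evolve(np.zeros((64, 64), complex), ilap3_2d_64, schedule, 400)
    fp = wg.scalar_fixed_point(I, tol=1e-14)
    assert np.max(np.abs(Z - fp.z_star)) < 1e-8


def test_evolve_deterministic_with_seeded_noise(ilap3_2d_64):
    src = SourceSpec(site=(10, 12), kind="white_noise", amplitude=1e-2, seed=5)
    schedule = InputSchedule(constant=0.0, sources=[src])
    snaps1, Z1 = evolve(np.zeros((64, 64), complex), ilap3_2d_64, schedule, 50, record_every=25)
    snaps2, Z2 = evolve(np.zeros((64, 64), complex), ilap3_2d_64, schedule, 50, record_every=25)
    assert np.array_equal(Z1, Z2)
    for (n1, a), (n2, b) in zip(snaps1, snaps2):
        assert n1 == n2 and np.array_equal(a, b)


def test_evolve_single_step_reduces_to_step(ilap3_2d_64):
    Z0 = random_field((64, 64), seed=8, scale=0.1)
    I = random_field((64, 64), seed=9, scale=0.01)
    _, Z1 = evolve(Z0, ilap3_2d_64, InputSchedule(constant=I), 1)
    assert np.array_equal(Z1, step(Z0, ilap3_2d_64, I))


def test_tone_source_injects_alpha_lambda_to_the_n():
    lam = np.exp(0.3j)
    src = SourceSpec(site=(3,), kind="tone", amplitude=0.5, frequency=lam)
    schedule = InputSchedule(constant=0.0, sources=[src])
    buf = np.zeros((8,), complex)
    schedule.add_to(buf, 4, schedule.fresh_rngs())
    assert buf[3] == pytest.approx(0.5 * lam**4)
    assert np.all(buf[:3] == 0)


class TestLinearStep:
    def test_unitary_when_gamma_is_one(self, ilap3_2d_64):
        dZ = random_field((64, 64), seed=11)
        out = linear_step(dZ, 1.0, ilap3_2d_64)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(dZ), abs=1e-10)

    def test_uniform_gamma_contracts_norm_geometrically(self, ilap3_2d_64):
        g = 0.85
        dZ = random_field((64, 64), seed=12)
        n0 = np.linalg.norm(dZ)
        for n in range(1, 21):
            dZ = linear_step(dZ, g, ilap3_2d_64)
            assert np.linalg.norm(dZ) == pytest.approx(g**n * n0, abs=1e-10 * n0)

    def test_exact_linearity_in_forcing_amplitude(self, ilap3_2d_64):
        forcing = random_field((64, 64), seed=13, scale=1e-3)
        dZ = random_field((64, 64), seed=14, scale=1e-3)
        a = linear_step(dZ, 0.7, ilap3_2d_64, forcing)
        b = linear_step(2 * dZ, 0.7, ilap3_2d_64, 2 * forcing)
        assert np.array_equal(b, 2 * a)

    def _tone_discrepancy(self, U, gamma_value, alpha, n_steps=60):
        gamma = np.full((64, 64), gamma_value)
        res = wg.design_input(gamma, U)
        lam = wg.pick_eigenfrequency(U, (16, 16))
        delta = np.zeros((64, 64), complex)
        delta[32, 32] = 1.0
        Z = res.z_star.astype(complex).copy()
        dZ = np.zeros((64, 64), complex)
        for n in range(n_steps):
            tone = alpha * lam**n * delta
            Z = step(Z, U, res.i_star + tone)
            dZ = linear_step(dZ, gamma, U, tone)
        return np.linalg.norm(Z - res.z_star - dZ) / alpha

    def test_linearization_error_scales_quadratically_on_quiescent_state(
        self, ilap3_2d_64
    ):
        """Richardson check around Z* = 0 (Gamma == 1): the full map matches
        the linear map to first order, so the normalized discrepancy drops
        ~100x when the amplitude drops 10x."""
        d1 = self._tone_discrepancy(ilap3_2d_64, 1.0, 1e-2)
        d2 = self._tone_discrepancy(ilap3_2d_64, 1.0, 1e-3)
        assert 30 < d1 / d2 < 300

    def test_scalar_slope_law_is_approximate_on_active_background(
        self, ilap3_2d_64
    ):
        """On a nonzero background the scalar slope Gamma drops the conjugate
        term of the (non-holomorphic) Jacobian, so the residual against the
        full map is first order in the amplitude — it bounds the wave but is
        not the exact tangent map.  The normalized discrepancy is then
        amplitude-independent."""
        d1 = self._tone_discrepancy(ilap3_2d_64, 0.8, 1e-3)
        d2 = self._tone_discrepancy(ilap3_2d_64, 0.8, 1e-4)
        assert 0.5 < d1 / d2 < 2.0


class TestModulatedStep:
    def test_near_identity_for_small_amplitudes(self, ilap3_2d_64):
        dZ = random_field((64, 64), seed=20, scale=1e-4)
        out = modulated_step(dZ, np.ones((64, 64)), ilap3_2d_64)
        rel = abs(np.linalg.norm(out) - np.linalg.norm(dZ)) / np.linalg.norm(dZ)
        assert rel < 1e-4

    def test_supercritical_growth_saturates(self, ilap3_2d_64):
        gamma = np.full((64, 64), 1.2)
        dZ = random_field((64, 64), seed=21, scale=1e-6)
        n0 = np.linalg.norm(dZ)
        norms = []
        for _ in range(400):
            dZ = modulated_step(dZ, gamma, ilap3_2d_64)
            norms.append(np.linalg.norm(dZ))
        assert norms[-1] > 1e3 * n0  # grew from tiny seed
        assert np.max(np.abs(dZ)) < 1.0  # sigmoid bounds every site
        # saturated: final norms stable within a few percent
        assert abs(norms[-1] - norms[-20]) < 0.1 * norms[-1]

    def test_subcritical_decay(self, ilap3_2d_64):
        dZ = random_field((64, 64), seed=22, scale=0.1)
        for _ in range(50):
            dZ = modulated_step(dZ, np.full((64, 64), 0.2), ilap3_2d_64)
        assert np.max(np.abs(dZ)) < 1e-30

    def test_nonpositive_gamma_rejected(self, ilap3_2d_64):
        with pytest.raises(ValueError, match="> 0"):
            modulated_step(np.zeros((64, 64), complex), np.zeros((64, 64)), ilap3_2d_64)
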