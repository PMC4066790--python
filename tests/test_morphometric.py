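"""Morphometric fit and the SPT hard-sphere calibration source."""

import numpy as np
import pytest

from hydromorph import (
    HardSphereEntropyTable,
    MorphoMeasures,
    ProbeSpec,
    SoluteBody,
    accessible_measures,
    fit_ma_coefficients,
    hydration_entropy,
    spt_hs_entropy,
    spt_table,
)
from hydromorph.constants import DEFAULT_ETA, RHO_WATER
from hydromorph.morphometric import MACoefficients


def cubic_table(a, b, c, e, dU, dS=2.8):
    R = (np.asarray(dU) + dS) / 2
    s = (a * 4 * np.pi * R**3 / 3 + b * 4 * np.pi * R**2
         + c * 4 * np.pi * R + e * 4 * np.pi)
    return HardSphereEntropyTable(dU=dU, s=s, dS=dS)


class TestFit:
    def test_exact_cubic_recovery(self):
        dU = np.linspace(1, 12, 12)
        coeffs = fit_ma_coefficients(cubic_table(-0.03, 0.2, -0.1, 0.05, dU))
        assert np.allclose(coeffs.as_array(), [-0.03, 0.2, -0.1, 0.05],
                           rtol=1e-10, atol=1e-12)
        assert coeffs.residual_rms < 1e-8

    def test_row_order_invariance(self):
        dU = np.linspace(0.5, 10, 15)
        t = cubic_table(-0.03, 0.2, -0.1, 0.05, dU)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(dU))
        t2 = HardSphereEntropyTable(dU=t.dU[perm], s=t.s[perm], dS=t.dS)
        assert np.allclose(fit_ma_coefficients(t).as_array(),
                           fit_ma_coefficients(t2).as_array())

    def test_spt_table_is_exactly_cubic(self):
        t = spt_table(dU_grid=np.linspace(0.5, 8, 25), eta=0.3831)
        assert fit_ma_coefficients(t).residual_rms < 1e-10

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError, match="underdetermined"):
            HardSphereEntropyTable(dU=[1.0, 1.0, 2.0, 2.0], s=[0, 0, 0, 0])

    def test_noise_perturbs_coefficients_continuously(self):
        # least squares is linear in the data: the coefficient perturbation
        # scales with the noise amplitude and no sign flips as sigma -> 0
        dU = np.linspace(0.5, 12, 30)
        base = cubic_table(-0.03, 0.2, -0.1, 0.05, dU)
        c0 = fit_ma_coefficients(base).as_array()
        rng = np.random.default_rng(7)
        noise = rng.normal(size=len(dU))

        def delta(sigma):
            t = HardSphereEntropyTable(dU=dU, s=base.s + sigma * noise, dS=base.dS)
            c = fit_ma_coefficients(t).as_array()
            assert np.array_equal(np.sign(c), np.sign(c0))
            return c - c0

        d2, d4, d6 = delta(1e-2), delta(1e-4), delta(1e-6)
        assert np.allclose(d4, d2 * 1e-2, rtol=1e-6, atol=1e-12)
        assert np.all(np.abs(d6) < np.abs(d2))


class TestSPT:
    def test_point_solute_boundary_value(self):
        # dU = 0: cavity radius dS/2 excludes solvent centers from one
        # solvent-sphere volume -> S/kB = ln(1 - eta) exactly
        for eta in (0.1, 0.3, 0.5):
            assert spt_hs_entropy(0.0, 2.8, eta) == pytest.approx(np.log(1 - eta), abs=1e-12)

    def test_dilute_limit_is_pure_volume_term(self):
        coeffs = fit_ma_coefficients(spt_table(eta=1e-6))
        rho = 6e-6 / (np.pi * 2.8**3)
        assert coeffs.C1 == pytest.approx(-rho, rel=1e-3)
        # other coefficients vanish relative to the volume term's scale
        assert abs(coeffs.C2) < 1e-3 * abs(coeffs.C1)

    def test_unphysical_packing_fraction(self):
        for eta in (-0.1, 0.0, 0.74, 1.0):
            with pytest.raises(ValueError, match="unphysical packing fraction"):
                spt_hs_entropy(1.0, 2.8, eta)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            spt_hs_entropy(-1.0, 2.8, 0.3)

    def test_monte_carlo_insertion_oracle(self):
        """Trial insertion into an equilibrated hard-sphere fluid.

        -ln(acceptance fraction) is the exact cavity work; classic SPT is
        accurate to ~1-2% at these densities, so agreement is asserted at
        2.5% relative (the MC sampling error itself is ~0.2%).
        """
        eta, dU, dS = 0.2, 2.0, 2.8
        rng = np.random.default_rng(42)
        n_side, sweeps = 6, 300
        N = n_side**3
        L = (np.pi * N / (6 * eta)) ** (1 / 3)  # solvent diameter = 1
        g = (np.arange(n_side) + 0.5) * L / n_side
        pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T.copy()
        step = 0.15
        for _ in range(sweeps):
            for i in range(N):
                trial = (pts[i] + rng.uniform(-step, step, 3)) % L
                d = pts - trial
                d -= L * np.round(d / L)
                d2 = (d * d).sum(1)
                d2[i] = 9.0
                if d2.min() >= 1.0:
                    pts[i] = trial
        R = (dU / dS + 1.0) / 2.0  # center-exclusion radius in solvent diameters
        accepted, trials = 0, 0
        for _ in range(40):
            t = rng.uniform(0, L, (20000, 3))
            d = pts[None, :, :] - t[:, None, :]
            d -= L * np.round(d / L)
            accepted += ((d * d).sum(-1).min(1) >= R * R).sum()
            trials += 20000
        bw_mc = -np.log(accepted / trials)
        bw_spt = -spt_hs_entropy(dU, dS, eta)
        assert bw_spt == pytest.approx(bw_mc, rel=0.025)


class TestHydrationEntropy:
    def test_zero_coefficients(self, single_sphere, water_probe):
        m = accessible_measures(single_sphere, water_probe, 0.3)
        zero = MACoefficients(0, 0, 0, 0)
        assert hydration_entropy(m, zero) == 0.0

    def test_sphere_consistency_with_fit_source(self, spt_coeffs):
        for dU in (1.0, 5.0, 14.0):
            R = (dU + 2.8) / 2
            m = MorphoMeasures(4 * np.pi * R**3 / 3, 4 * np.pi * R**2,
                               4 * np.pi * R, 4 * np.pi)
            assert hydration_entropy(m, spt_coeffs) == pytest.approx(
                spt_hs_entropy(dU), abs=1e-8)

    def test_far_separated_additivity(self, spt_coeffs, water_probe):
        one = SoluteBody(np.zeros((1, 3)), np.array([2.8]))
        two = SoluteBody(np.array([[0.0, 0, 0], [80.0, 0, 0]]), np.full(2, 2.8))
        s1 = hydration_entropy(accessible_measures(one, water_probe, 0.25), spt_coeffs)
        s2 = hydration_entropy(accessible_measures(two, water_probe, 0.25), spt_coeffs)
        assert s2 == pytest.approx(2 * s1, rel=1e-3)

    def test_liquid_eta_signs(self, spt_coeffs, water_probe, touching_unit_pair):
        # insertion always costs solvent entropy; association recovers some
        assert spt_coeffs.C1 < 0
        bodies = [
            SoluteBody(np.zeros((1, 3)), np.array([2.8])),
            SoluteBody(np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.full(2, 3.2)),
        ]
        for b in bodies:
            s = hydration_entropy(accessible_measures(b, water_probe, 0.25), spt_coeffs)
            assert s < 0
        a = SoluteBody(np.zeros((1, 3)), np.array([2.8]))
        b = SoluteBody(np.array([[3.0, 0, 0]]), np.array([2.8]))
        bound = a + b
        sa = hydration_entropy(accessible_measures(a, water_probe, 0.25), spt_coeffs)
        sb = hydration_entropy(accessible_measures(b, water_probe, 0.25), spt_coeffs)
        sc = hydration_entropy(accessible_measures(bound, water_probe, 0.25), spt_coeffs)
        assert sc - sa - sb > 0

    def test_default_eta_matches_water_density(self):
        assert DEFAULT_ETA == pytest.approx(np.pi * RHO_WATER * 2.8**3 / 6, abs=1e-12)
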