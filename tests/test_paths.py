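"""Free-energy function, path decomposition, conversions, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydromorph import (
    FitterInput,
    SpeciesThermo,
    WaterProperties,
    ensemble_summary,
    fitter_conf_entropy,
    free_energy,
    isochoric_to_isobaric,
    kd_to_binding_free_energy,
    path2_from_additivity,
    path_delta,
)
from hydromorph.constants import R_KCAL
from hydromorph.paths import isobaric_correction

comp = st.floats(-100, 100, allow_nan=False, allow_infinity=False)


def species(label="s", **kw):
    base = dict(E_LJ=0.0, E_ES=0.0, eps_VH_LJ=0.0, eps_VH_ES=0.0, TS_VH=0.0)
    base.update(kw)
    return SpeciesThermo(label=label, **base)


@st.composite
def random_species(draw, label="s"):
    return species(
        label,
        E_LJ=draw(comp), E_ES=draw(comp), eps_VH_LJ=draw(comp),
        eps_VH_ES=draw(comp), TS_VH=draw(comp), E_B=draw(comp), TS_C=draw(comp),
    )


class TestFreeEnergy:
    def test_zero_components(self):
        assert free_energy(species()) == 0.0

    def test_component_arithmetic(self):
        s = species(E_B=1, E_LJ=1, E_ES=1, eps_VH_LJ=1, eps_VH_ES=1,
                    TS_C=0.0, TS_VH=2.0)
        assert free_energy(s) == pytest.approx(3.0)

    def test_absent_optionals_count_as_zero(self):
        assert free_energy(species(E_LJ=2.0)) == free_energy(
            species(E_LJ=2.0, E_B=0.0, TS_C=0.0))


class TestPathDelta:
    def test_complex_equal_to_part_gives_zeros(self):
        s = species("x", E_LJ=3, E_ES=-2, eps_VH_LJ=1, eps_VH_ES=4, TS_VH=-7)
        r = path_delta(s, [s], "I")
        assert r.dG == r.dE_total == r.mTdS_VH == 0.0

    @given(random_species("c"), random_species("a"), random_species("b"))
    @settings(max_examples=50, deadline=None)
    def test_internal_identities_exact(self, c, a, b):
        for path in ("I", "II", "III"):
            r = path_delta(c, [a, b], path)
            r.validate(tol=1e-9)

    def test_path_one_forces_rigid_terms_to_zero(self):
        c = species("c", E_B=50.0, TS_C=10.0, E_LJ=1.0)
        p = species("p", E_B=3.0, TS_C=2.0)
        r1 = path_delta(c, [p], "I")
        assert r1.dE_B == 0.0 and r1.mTdS_C == 0.0 and not r1.s_c_omitted
        r3 = path_delta(c, [p], "III")
        assert r3.dE_B == pytest.approx(47.0)
        assert r3.mTdS_C == pytest.approx(-8.0)

    def test_omitted_conformational_entropy_flagged(self):
        r = path_delta(species("c"), [species("p")], "II")
        assert r.s_c_omitted and r.mTdS_C == 0.0

    def test_empty_parts(self):
        with pytest.raises(ValueError, match="empty parts"):
            path_delta(species(), [], "I")


class TestAdditivity:
    @given(random_species("m"), random_species("a"), random_species("b"),
           random_species("q"))
    @settings(max_examples=30, deadline=None)
    def test_componentwise_sum(self, c, a, b, q):
        p1 = path_delta(c, [a, b], "I", model_label="m")
        p3 = path_delta(b, [q], "III", model_label="m")
        p2 = path2_from_additivity(p1, p3)
        assert p2.path_id == "II"
        for f in ("dG", "dE_total", "mTdS_VH", "dE_B", "d_LJ_component",
                  "d_ES_component", "dE_LJ", "dEps_LJ", "dE_ES", "dEps_ES"):
            assert getattr(p2, f) == pytest.approx(
                getattr(p1, f) + getattr(p3, f), rel=1e-12, abs=1e-12)
        p2.validate(tol=1e-9)

    def test_zero_third_path_relabels(self):
        p1 = path_delta(species("c", E_LJ=5.0), [species("a")], "I", model_label="m")
        p3 = path_delta(species("z"), [species("z")], "III", model_label="m")
        p2 = path2_from_additivity(p1, p3)
        assert p2.dG == p1.dG and p2.path_id == "II"

    def test_label_mismatch(self):
        p1 = path_delta(species("c"), [species("a")], "I", model_label="m1")
        p3 = path_delta(species("c"), [species("a")], "III", model_label="m2")
        with pytest.raises(ValueError, match="label mismatch"):
            path2_from_additivity(p1, p3)

    def test_wrong_path_ids(self):
        p1 = path_delta(species("c"), [species("a")], "I", model_label="m")
        with pytest.raises(ValueError):
            path2_from_additivity(p1, p1)


class TestIsobaricConversion:
    def test_zero_volume_change_is_identity(self):
        dh, dspb = isochoric_to_isobaric(3.2, -5.0, 0.0)
        assert dh == 3.2 and dspb == -5.0

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_hydration_free_energy_invariant(self, de, ds, dv):
        # dMu_H = dEps - T dS_VH = dH - T dS_PH must hold exactly
        w = WaterProperties()
        kbt = R_KCAL * w.T
        dh, dspb = isochoric_to_isobaric(de, ds, dv, w)
        mu_iso = de - kbt * ds
        mu_bar = dh - kbt * dspb
        assert mu_iso == pytest.approx(mu_bar, rel=1e-9, abs=1e-9)

    def test_reported_correction_magnitude(self):
        # dV_PH/dS^3 = 5.51 with standard water properties at 298 K
        assert isobaric_correction() * 5.51 == pytest.approx(2.92, rel=0.03)

    def test_invalid_water_properties(self):
        with pytest.raises(ValueError):
            WaterProperties(alpha=-1e-4)


class TestExperimentalComparison:
    def test_standard_state_zero(self):
        assert kd_to_binding_free_energy(1.0) == 0.0

    def test_micromolar_binder(self):
        assert kd_to_binding_free_energy(1e-6, 298.0) == pytest.approx(-8.18, abs=0.01)

    def test_sub_molar_kd_is_negative(self):
        assert kd_to_binding_free_energy(1e-5) < 0

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            kd_to_binding_free_energy(0.0)

    def test_fitter_equal_radii_no_loss(self):
        f = FitterInput(N_r=12, observations=((303, 1.2, 1.2), (343, 1.1, 1.1)))
        assert fitter_conf_entropy(f) == pytest.approx(0.0, abs=1e-12)

    def test_fitter_linearity_in_residues(self):
        obs = ((303, 1.5, 1.0), (323, 1.4, 1.0), (343, 1.3, 1.0))
        one = fitter_conf_entropy(FitterInput(N_r=6, observations=obs))
        two = fitter_conf_entropy(FitterInput(N_r=12, observations=obs))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_fitter_reference_magnitude(self):
        # constant radius ratio 1.513 over 12 residues at 298 K
        obs = ((303, 1.513, 1.0), (323, 1.513, 1.0), (343, 1.513, 1.0))
        v = fitter_conf_entropy(FitterInput(N_r=12, observations=obs, T_target=298))
        assert v == pytest.approx(8.83, abs=0.02)

    def test_fitter_input_validation(self):
        with pytest.raises(ValueError, match="unphysical radii"):
            FitterInput(N_r=12, observations=((303, -1.0, 1.0), (343, 1.0, 1.0)))
        with pytest.raises(ValueError, match="linear fit"):
            FitterInput(N_r=12, observations=((303, 1.0, 1.0),))


class TestEnsembleSummary:
    def _result(self, dg, label="m"):
        return path_delta(species(label, E_LJ=dg), [species("z")], "I",
                          model_label=label)

    def test_single_result(self):
        s = ensemble_summary([self._result(-4.0)])
        assert s.mean == s.min == s.max == -4.0

    def test_shift_and_ranking(self):
        rs = [self._result(v, f"m{k}") for k, v in enumerate((3.0, -5.0, 1.0))]
        s = ensemble_summary(rs, shift=2.0)
        assert s.mean == pytest.approx(2.0 - 1.0 / 3.0)
        assert s.min == -3.0 and s.max == 5.0
        assert s.ranking == ["m1", "m2", "m0"]

    def test_empty(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_summary([])
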