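"""Random-coil generator: sampling ranges, rebuild fidelity, clash filter."""

import numpy as np
import pytest

from hydromorph import (
    DihedralRanges,
    SpeciesThermo,
    build_template,
    clash_filter,
    ensemble_reference_state,
    sample_random_coil,
)
from hydromorph.conformers import B_C_N, B_CA_C, B_N_CA, measure_dihedrals


@pytest.fixture(scope="module")
def small_ensemble(p16_template):
    return [sample_random_coil(p16_template, seed=s) for s in range(60)]


class TestSampling:
    def test_determinism(self, p16_template):
        a = sample_random_coil(p16_template, seed=123)
        b = sample_random_coil(p16_template, seed=123)
        assert np.array_equal(a.dihedrals, b.dihedrals)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_all_dihedrals_in_allowed_regions(self, small_ensemble):
        r = DihedralRanges()
        for conf in small_ensemble:
            for i, aa in enumerate(conf.sequence):
                assert r.contains(aa, "phi", conf.dihedrals[i, 0]), (i, aa)
                assert r.contains(aa, "psi", conf.dihedrals[i, 1]), (i, aa)

    def test_proline_pinned(self, small_ensemble):
        for conf in small_ensemble:
            for i, aa in enumerate(conf.sequence):
                if aa == "P":
                    assert tuple(conf.dihedrals[i]) == (-65.0, 180.0)

    def test_forbidden_psi_gap_never_sampled(self, small_ensemble):
        # generic Psi excludes (-150, -90)
        for conf in small_ensemble:
            for i, aa in enumerate(conf.sequence):
                if aa not in "GP":
                    psi = conf.dihedrals[i, 1]
                    assert not (-150.0 < psi < -90.0)

    def test_missing_backbone_atom_names_residue(self, p16_template):
        broken = sample_random_coil(p16_template, seed=0)
        keep = [k for k, (nm, ri) in enumerate(zip(broken.atom_names, broken.atom_res))
                if not (ri == 3 and nm == "CA")]
        broken.atom_names = [broken.atom_names[k] for k in keep]
        broken.atom_res = broken.atom_res[keep]
        broken.coordinates = broken.coordinates[keep]
        with pytest.raises(KeyError, match="residue 3"):
            sample_random_coil(broken, seed=1)


class TestRebuildFidelity:
    def test_backbone_bond_lengths_exact(self, p16_template):
        conf = sample_random_coil(p16_template, seed=5)
        x = conf.coordinates
        for i in range(len(conf.sequence)):
            n, ca, c = (conf.backbone_index(i, a) for a in ("N", "CA", "C"))
            assert np.linalg.norm(x[ca] - x[n]) == pytest.approx(B_N_CA, rel=1e-9)
            assert np.linalg.norm(x[c] - x[ca]) == pytest.approx(B_CA_C, rel=1e-9)
            if i + 1 < len(conf.sequence):
                n1 = conf.backbone_index(i + 1, "N")
                assert np.linalg.norm(x[n1] - x[c]) == pytest.approx(B_C_N, rel=1e-9)

    def test_measured_dihedrals_match_sampled(self, p16_template):
        conf = sample_random_coil(p16_template, seed=9)
        measured = measure_dihedrals(conf)
        diff = ((measured - conf.dihedrals + 180.0) % 360.0) - 180.0
        assert np.nanmax(np.abs(diff)) < 1e-8

    def test_template_dihedrals_extended(self, p16_template):
        measured = measure_dihedrals(p16_template)
        for i, aa in enumerate(p16_template.sequence):
            expect = (-65.0, 180.0) if aa == "P" else (-135.0, 135.0)
            if i > 0:
                assert measured[i, 0] == pytest.approx(expect[0], abs=1e-6)
            d_psi = ((measured[i, 1] - expect[1] + 180.0) % 360.0) - 180.0
            assert abs(d_psi) < 1e-6


class TestClashFilter:
    def test_extended_template_retained(self, p16_template):
        retained, report = clash_filter([p16_template])
        assert len(retained) == 1 and not report.rejected

    def test_overlapping_atoms_rejected_with_pair(self, p16_template):
        conf = sample_random_coil(p16_template, seed=2)
        bad = sample_random_coil(p16_template, seed=2)
        i = bad.backbone_index(0, "N")
        j = bad.backbone_index(len(bad.sequence) - 1, "O")
        bad.coordinates[j] = bad.coordinates[i] + np.array([0.1, 0.0, 0.0])
        bad.label = "clashed"
        retained, report = clash_filter([conf, bad])
        assert [c.label for c in retained] == [conf.label]
        label, pair, dist = report.rejected[0]
        assert label == "clashed" and dist == pytest.approx(0.1, abs=1e-9)

    def test_retention_count_reproducible_for_seed_batch(self, p16_template):
        # regression fixture: 200 seeded draws of the prion-fragment coil
        # ensemble under the default overlap criterion
        ens = [sample_random_coil(p16_template, seed=s) for s in range(200)]
        retained, report = clash_filter(ens)
        assert report.n_input == 200
        assert report.n_retained == 170
        retained2, report2 = clash_filter(ens)
        assert report2.n_retained == report.n_retained

    def test_energy_threshold_criterion(self, p16_template):
        ens = [sample_random_coil(p16_template, seed=s) for s in range(20)]
        loose, _ = clash_filter(ens, energy_threshold=1e12)
        tight, _ = clash_filter(ens, energy_threshold=-1e12)
        assert len(loose) == 20 and len(tight) == 0

    def test_retained_conformers_have_finite_lj(self, small_ensemble):
        retained, _ = clash_filter(small_ensemble)
        assert retained
        for conf in retained:
            sig = conf.sigmas()
            diff = conf.coordinates[:, None, :] - conf.coordinates[None, :, :]
            r = np.sqrt((diff**2).sum(-1))
            iu, ju = np.triu_indices(len(conf), k=1)
            sij = 0.5 * (sig[iu] + sig[ju])
            sr6 = (sij / r[iu, ju]) ** 6
            e = np.sum(4 * 0.1 * (sr6**2 - sr6))
            assert np.isfinite(e)


class TestReferenceState:
    def _thermo(self, x, label="t"):
        return SpeciesThermo(label=label, E_LJ=x, E_ES=2 * x, eps_VH_LJ=-x,
                             eps_VH_ES=0.5 * x, TS_VH=-3 * x, E_B=x, TS_C=x)

    def test_single_conformer_is_itself(self):
        t = self._thermo(2.5)
        ref = ensemble_reference_state([t])
        for f in ("E_LJ", "E_ES", "eps_VH_LJ", "eps_VH_ES", "TS_VH", "E_B", "TS_C"):
            assert getattr(ref, f) == getattr(t, f)

    def test_opposite_components_average_to_zero(self):
        ref = ensemble_reference_state([self._thermo(3.0), self._thermo(-3.0)])
        assert ref.E_LJ == 0.0 and ref.TS_VH == 0.0

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(31)
        mu, sigma, n = -40.0, 5.0, 103
        vals = rng.normal(mu, sigma, n)
        ref = ensemble_reference_state([self._thermo(v) for v in vals])
        se = sigma / np.sqrt(n)
        assert abs(ref.E_LJ - mu) < 4 * se

    def test_partial_optionals_omitted(self):
        a = self._thermo(1.0)
        b = SpeciesThermo(label="b", E_LJ=1, E_ES=2, eps_VH_LJ=-1,
                          eps_VH_ES=0.5, TS_VH=-3)
        ref = ensemble_reference_state([a, b])
        assert ref.E_B is None and ref.TS_C is None

    def test_empty_ensemble(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_reference_state([])
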