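import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gagfold import synthetic_data as sd
from gagfold.decoys import RG_COEFF, RG_EXPONENT, RG_SLACK
from gagfold.relaxation import SpinParams, estimate_tc
from gagfold.sap_align import align
from gagfold.structures import segment_list, ss_composition

SP700 = SpinParams(700.0)


class TestIdealHelix:
    def test_single_residue(self):
        assert len(sd.build_ideal_helix(1)) == 1

    def test_consecutive_spacing(self):
        h = sd.build_ideal_helix(20)
        steps = np.linalg.norm(np.diff(h.ca_coords, axis=0), axis=1)
        assert steps.min() > 3.8 and steps.max() < 3.9

    def test_assigned_helical(self):
        h = sd.build_ideal_helix(12)
        assert h.ss.count("H") >= 8


class TestBuildBundle:
    def test_matches_requested_layout(self, n_bundle):
        segs = [s for s in segment_list(n_bundle.ss) if s[0] == "H"]
        # four helical segments, each recovered over most of its length
        assert len(segs) == 4
        assert sum(n for _, n in segs) >= 0.7 * sum(
            n for c, n in sd.N_LAYOUT if c == "H"
        )

    def test_seeded_determinism(self):
        spec = sd.BundleSpec(sd.N_LAYOUT, seed=8)
        a, b = sd.build_bundle(spec), sd.build_bundle(spec)
        np.testing.assert_array_equal(a.ca_coords, b.ca_coords)

    def test_compact_and_clash_free(self, c_bundle):
        xyz = c_bundle.ca_coords
        n = len(xyz)
        rg = np.sqrt(np.mean(np.sum((xyz - xyz.mean(0)) ** 2, axis=1)))
        assert rg <= RG_SLACK * RG_COEFF * n**RG_EXPONENT
        i, j = np.triu_indices(n, k=3)
        assert cdist(xyz, xyz)[i, j].min() >= 4.0
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        assert steps.min() > 2.8 and steps.max() < 4.2


class TestPerturb:
    def test_zero_sigma_identity(self, n_bundle):
        out = sd.perturb(n_bundle, 0.0, seed=1)
        np.testing.assert_array_equal(out.ca_coords, n_bundle.ca_coords)

    def test_seeded_determinism(self, n_bundle):
        a = sd.perturb(n_bundle, 0.7, seed=5)
        b = sd.perturb(n_bundle, 0.7, seed=5)
        np.testing.assert_array_equal(a.ca_coords, b.ca_coords)

    def test_expected_rmsd(self):
        big = sd.build_ideal_helix(100)
        sigma = 0.8
        rmsds = [
            np.sqrt(np.mean(np.sum(
                (sd.perturb(big, sigma, seed=s).ca_coords - big.ca_coords) ** 2, axis=1
            )))
            for s in range(10)
        ]
        assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(3), rel=0.1)


class TestHomologyQuartet:
    def test_seeded_determinism(self):
        q1, q2 = sd.make_homology_quartet(77), sd.make_homology_quartet(77)
        np.testing.assert_array_equal(q1.spuma_n.ca_coords, q2.spuma_n.ca_coords)
        np.testing.assert_array_equal(q1.ortho_c.ca_coords, q2.ortho_c.ca_coords)

    def test_kin_pairs_share_composition(self):
        q = sd.make_homology_quartet(31)
        assert ss_composition(q.spuma_c.ss).counts == ss_composition(q.ortho_c.ss).counts
        assert segment_list(q.spuma_n.ss) == segment_list(q.ortho_n.ss)

    def test_forward_kin_outscores_cross_pair(self):
        hits = 0
        for seed in range(10):
            q = sd.make_homology_quartet(1000 + seed)
            if align(q.spuma_n, q.ortho_n).score_norm > align(
                q.spuma_n, q.ortho_c
            ).score_norm:
                hits += 1
        assert hits >= 9


class TestGenerateSEDataset:
    def setup_method(self):
        from gagfold.hydrodynamics import BuoyancyParams

        self.p = BuoyancyParams(11894.0, 0.7312, 1.005, 293.0)

    def test_noise_free_matches_forward_model(self):
        from gagfold.hydrodynamics import predict_se_profile, rpm_to_omega
        from dataclasses import replace

        profs = sd.generate_se_dataset(self.p, 0.9e-6, loadings=(5e-5,),
                                       speeds=(20000,), noise_sd_frac=0.0, seed=0)
        pr = profs[0]
        pp = replace(self.p, omega=rpm_to_omega(20000))
        expected = predict_se_profile(pp, "monomer_dimer", 5e-5, pr.radii,
                                      pr.r0, K_A=1 / 0.9e-6)
        np.testing.assert_allclose(pr.signal, expected)

    def test_seeded_determinism_and_geometry(self):
        a = sd.generate_se_dataset(self.p, 0.9e-6, (5e-5,), (20000,), 0.005, seed=4)
        b = sd.generate_se_dataset(self.p, 0.9e-6, (5e-5,), (20000,), 0.005, seed=4)
        np.testing.assert_array_equal(a[0].signal, b[0].signal)
        assert np.all(np.diff(a[0].radii) > 0)
        assert a[0].radii[0] >= 6.9 and a[0].radii[-1] <= 7.4


class TestGenerateRelaxationDataset:
    def test_noise_free_records_invert_exactly(self):
        records = sd.generate_relaxation_dataset(14.1e-9, SP700, 10, 0.0, 0.0, seed=0)
        for rec in records:
            assert estimate_tc(rec, SP700) * 1e9 == pytest.approx(14.1, abs=0.01)

    def test_loop_fraction_below_cutoff(self):
        records = sd.generate_relaxation_dataset(14.1e-9, SP700, 50, 0.0, 0.2, seed=1)
        assert sum(r.noe < 0.75 for r in records) == 10

    def test_seeded_determinism(self):
        a = sd.generate_relaxation_dataset(14.1e-9, SP700, 20, 0.02, 0.1, seed=9)
        b = sd.generate_relaxation_dataset(14.1e-9, SP700, 20, 0.02, 0.1, seed=9)
        assert [(r.T1, r.T2, r.noe) for r in a] == [(r.T1, r.T2, r.noe) for r in b]
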