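import math

import numpy as np
import pytest

from gagfold.hydrodynamics import (
    BuoyancyParams,
    R_GAS_CGS,
    SEProfile,
    fit_se_global,
    ka_to_kd,
    predict_se_profile,
    profiles_from_table,
    reduced_buoyant_mass,
    rpm_to_omega,
)
from gagfold.synthetic_data import generate_se_dataset

CTD_PARAMS = dict(M=11894.0, vbar=0.7312, rho=1.005, T=293.0)


class TestReducedBuoyantMass:
    def test_neutral_buoyancy_is_zero(self):
        p = BuoyancyParams(10000, 1.0, 1.0, 293.0, omega=rpm_to_omega(20000))
        assert reduced_buoyant_mass(p) == 0.0

    def test_at_rest_is_zero(self):
        p = BuoyancyParams(10000, 0.73, 1.0, 293.0, omega=0.0)
        assert reduced_buoyant_mass(p) == 0.0

    def test_closed_form_hand_computation(self):
        # independent arithmetic: M(1-vbar*rho)*omega^2 / (2RT) in CGS
        omega = 20000 * 2 * math.pi / 60
        p = BuoyancyParams(**CTD_PARAMS, omega=omega)
        expected = 11894.0 * (1 - 0.7312 * 1.005) * omega**2 / (2 * R_GAS_CGS * 293.0)
        assert reduced_buoyant_mass(p) == pytest.approx(expected, rel=1e-12)
        assert reduced_buoyant_mass(p) == pytest.approx(0.283920, rel=1e-5)


class TestPredictProfile:
    def setup_method(self):
        self.radii = np.linspace(6.9, 7.4, 30)

    def test_zero_field_profile_is_flat(self):
        p = BuoyancyParams(**CTD_PARAMS, omega=0.0)
        sig = predict_se_profile(p, "monomer_dimer", 5e-5, self.radii, 6.9,
                                 K_A=1e6, baseline=0.1)
        assert np.ptp(sig) == pytest.approx(0.0, abs=1e-12)

    def test_no_association_is_single_exponential(self):
        p = BuoyancyParams(**CTD_PARAMS, omega=rpm_to_omega(20000))
        sig = predict_se_profile(p, "monomer_dimer", 5e-5, self.radii, 6.9, K_A=0.0)
        single = predict_se_profile(p, "single", 5e-5, self.radii, 6.9)
        np.testing.assert_allclose(sig, single)
        sigma = reduced_buoyant_mass(p)
        log_slope = np.diff(np.log(sig)) / np.diff(self.radii**2)
        np.testing.assert_allclose(log_slope, sigma, rtol=1e-9)

    def test_dimer_term_only_adds_signal(self):
        p = BuoyancyParams(**CTD_PARAMS, omega=rpm_to_omega(20000))
        with_dimer = predict_se_profile(p, "monomer_dimer", 5e-5, self.radii, 6.9, K_A=1e6)
        without = predict_se_profile(p, "monomer_dimer", 5e-5, self.radii, 6.9, K_A=0.0)
        assert np.all(with_dimer >= without)


class TestGlobalFit:
    def test_single_species_roundtrip(self):
        p = BuoyancyParams(20543.0, 0.7416, 1.005, 293.0)
        profiles = generate_se_dataset(p, 0.0, loadings=(3e-5, 6e-5),
                                       speeds=(15000, 20000, 25000),
                                       noise_sd_frac=0.0, seed=1)
        fit = fit_se_global(profiles, p, "single")
        assert fit.Mw == pytest.approx(20543.0, rel=1e-3)
        assert all(r < 1e-6 for r in fit.rms_per_profile)

    def test_mass_conservation_on_noise_free_data(self):
        p = BuoyancyParams(**CTD_PARAMS)
        loadings = (2e-5, 5e-5, 1e-4)
        profiles = generate_se_dataset(p, 0.9e-6, loadings=loadings,
                                       speeds=(15000, 20000, 25000),
                                       noise_sd_frac=0.0, seed=0)
        fit = fit_se_global(profiles, p, "monomer_dimer")
        # three profiles per loading, in loading order
        recovered = np.array(fit.c_refs).reshape(3, 3)
        for truth, got in zip(loadings, recovered):
            np.testing.assert_allclose(got, truth, rtol=5e-3)
        assert fit.K_A * fit.K_D == pytest.approx(1.0, rel=1e-12)

    def test_kd_recovery_with_noise(self):
        p = BuoyancyParams(**CTD_PARAMS)
        kds = []
        for seed in range(5):
            profiles = generate_se_dataset(p, 0.9e-6, loadings=(2e-5, 5e-5, 1e-4),
                                           speeds=(15000, 20000, 25000),
                                           noise_sd_frac=0.005, seed=seed)
            kds.append(fit_se_global(profiles, p, "monomer_dimer").K_D * 1e6)
        assert np.median(kds) == pytest.approx(0.9, rel=0.1)

    def test_single_model_on_dimerizing_data_shows_mass_drift(self):
        # apparent weight-average mass must grow with loading concentration
        p = BuoyancyParams(**CTD_PARAMS)
        mws = []
        for c0 in (2e-7, 9e-7, 5e-6, 5e-5):
            profiles = generate_se_dataset(p, 0.9e-6, loadings=(c0,),
                                           speeds=(15000, 20000, 25000),
                                           noise_sd_frac=0.0, seed=1)
            mws.append(fit_se_global(profiles, p, "single").Mw)
        assert all(a < b for a, b in zip(mws, mws[1:]))
        # apparent mass stays between monomer and dimer mass
        assert 11894.0 * 0.99 < mws[0] and mws[-1] < 2 * 11894.0 * 1.01

    def test_needs_two_profiles(self):
        p = BuoyancyParams(**CTD_PARAMS)
        profiles = generate_se_dataset(p, 0.0, loadings=(5e-5,), speeds=(20000,),
                                       noise_sd_frac=0.0, seed=0)
        with pytest.raises(ValueError):
            fit_se_global(profiles, p, "single")


class TestKaKd:
    def test_published_constant(self):
        assert ka_to_kd(1.1e6) * 1e6 == pytest.approx(0.9, abs=0.05)

    def test_identity(self):
        assert ka_to_kd(1.0) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ka_to_kd(0.0)


def test_profiles_from_table_grouping():
    import pandas as pd

    radii = np.linspace(6.9, 7.4, 25)
    rows = []
    for sid in ("a", "b"):
        for rpm in (15000, 20000):
            for r in radii:
                rows.append({"radius_cm": r, "signal": 1.0, "speed_rpm": rpm,
                             "sample_id": sid})
    profiles = profiles_from_table(pd.DataFrame(rows))
    assert len(profiles) == 4
    assert {p.sample_id for p in profiles} == {"a", "b"}
    with pytest.raises(ValueError):
        profiles_from_table(pd.DataFrame({"x": [1]}))
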