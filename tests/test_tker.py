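"""Kinetic-energy-release transform, Maxwell-Boltzmann and ion-dipole fits."""

import numpy as np
import pytest

import microsolv as m
from microsolv.exceptions import (
    BinningError,
    InsufficientSignalError,
    ParameterError,
    PreconditionError,
)
from microsolv.tker import mb_shape


class TestKEtoTKER:
    def test_zero_energy_maps_to_zero(self):
        assert m.ke_to_tker(0.0) == 0.0

    def test_linearity(self):
        e = np.array([10.0, 50.0, 200.0])
        np.testing.assert_allclose(m.ke_to_tker(3.0 * e), 3.0 * m.ke_to_tker(e))

    def test_water_loss_from_the_cluster(self):
        # E_K m_parent / (m_parent - m_fragment) for H2O off C8H7N(H2O)
        assert float(m.ke_to_tker(100.0)) == pytest.approx(115.38, abs=0.01)

    def test_fragment_heavier_than_parent_is_rejected(self):
        with pytest.raises(ParameterError):
            m.ke_to_tker(1.0, m_fragment_u=200.0, m_parent_u=135.0)


class TestBackgroundSubtraction:
    def make(self, counts, delay):
        edges = np.arange(0.0, 10.0 * (len(counts) + 1) - 1e-9, 10.0)
        return m.KESpectrum(edges, np.asarray(counts, float), delay_ps=delay)

    def test_single_spectrum_subtracted_from_itself_is_zero(self):
        s = self.make([3.0, 5.0, 2.0], -5.0)
        sub, bg = m.subtract_negative_delay_background([s])
        assert np.all(sub[0].counts == 0.0)
        np.testing.assert_array_equal(bg.counts, s.counts)

    def test_background_of_identical_spectra_equals_either(self):
        s1 = self.make([3.0, 5.0, 2.0], -5.0)
        s2 = self.make([3.0, 5.0, 2.0], -1.0)
        _, bg = m.subtract_negative_delay_background([s1, s2])
        np.testing.assert_array_equal(bg.counts, s1.counts)

    def test_round_trip_restores_input_exactly(self):
        rng = np.random.default_rng(0)
        spectra = [self.make(rng.poisson(50.0, 8), d) for d in (-9.0, -5.0, 20.0, 70.0)]
        sub, bg = m.subtract_negative_delay_background(spectra)
        for orig, s in zip(spectra, sub):
            np.testing.assert_array_equal(s.counts + bg.counts, orig.counts)

    def test_mismatched_binning_is_rejected(self):
        s1 = self.make([1.0, 2.0], -1.0)
        s2 = m.KESpectrum(np.array([0.0, 5.0, 10.0]), np.array([1.0, 2.0]), -2.0)
        with pytest.raises(BinningError):
            m.subtract_negative_delay_background([s1, s2])

    def test_requires_a_negative_delay_spectrum(self):
        with pytest.raises(PreconditionError):
            m.subtract_negative_delay_background([self.make([1.0, 2.0], 10.0)])


class TestMaxwellBoltzmann:
    edges = np.arange(0.0, 605.0, 5.0)

    def exact_spectrum(self, kT, form="3d", amp=1000.0):
        c = 0.5 * (self.edges[:-1] + self.edges[1:])
        return m.KESpectrum(self.edges, amp * mb_shape(c, kT, form))

    @pytest.mark.parametrize("form,factor", [("3d", 1.5), ("projected", 1.0)])
    def test_exact_histogram_recovers_characteristic_energy(self, form, factor):
        fit = m.fit_maxwell_boltzmann(self.exact_spectrum(50.0, form), form=form)
        assert fit.kT_mev == pytest.approx(50.0, rel=1e-3)
        assert fit.mean_mev == pytest.approx(factor * fit.kT_mev, rel=1e-12)

    def test_sampled_mean_matches_analytic_mean(self):
        # the analytic mean of sqrt(E) exp(-E/kT) is 3kT/2: check against
        # the empirical mean of gamma(3/2, kT) draws
        rng = np.random.default_rng(1)
        samples = rng.gamma(1.5, 30.0, size=200_000)
        assert samples.mean() == pytest.approx(1.5 * 30.0, rel=0.01)

    def test_monte_carlo_mean_recovery(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts, _ = np.histogram(rng.gamma(1.5, 30.0, size=100_000), bins=self.edges)
            fit = m.fit_maxwell_boltzmann(m.KESpectrum(self.edges, counts.astype(float)))
            assert fit.mean_mev == pytest.approx(45.0, rel=0.02)

    def test_nonpositive_total_signal_is_rejected(self):
        spec = m.KESpectrum(self.edges, np.full(self.edges.size - 1, -1.0))
        with pytest.raises(InsufficientSignalError):
            m.fit_maxwell_boltzmann(spec)


class TestIonDipolePotential:
    def test_perpendicular_geometry_gives_zero(self):
        assert m.ion_dipole_potential(490.0, theta_deg=90.0) == pytest.approx(0.0, abs=1e-15)

    def test_inverse_square_scaling(self):
        assert m.ion_dipole_potential(980.0) == pytest.approx(
            m.ion_dipole_potential(490.0) / 4.0, rel=1e-12
        )

    def test_equilibrium_cluster_geometry(self):
        # 1 e charge, 1.96 D dipole at 38 deg and 490 pm
        assert m.ion_dipole_potential(490.0) == pytest.approx(0.1928, abs=5e-4)

    def test_nonpositive_separation_is_rejected(self):
        with pytest.raises(ParameterError):
            m.ion_dipole_potential(0.0)


class TestTKEREvolution:
    def test_zero_speed_gives_constant_release(self, truth):
        model = m.IonDipoleModel(v_m_per_s=0.0)
        t = np.linspace(51.0, 300.0, 50)
        out = m.tker_evolution(model, t)
        np.testing.assert_allclose(out, model.asymptote_ev + model.v_eq_ev, rtol=1e-12)

    def test_asymptotic_release_is_below_50_mev(self):
        model = m.IonDipoleModel()
        assert model.asymptote_ev == pytest.approx(0.040, abs=1e-12)
        assert model.asymptote_ev < 0.050
        assert float(m.tker_evolution(model, 1e6)) == pytest.approx(0.040, abs=1e-4)

    def test_release_at_dissociation_onset(self):
        assert float(m.tker_evolution(m.IonDipoleModel(), 51.0)) == pytest.approx(
            0.233, abs=1e-3
        )

    def test_monotone_decay_bounded_by_asymptote(self):
        model = m.IonDipoleModel()
        t = np.linspace(51.0, 500.0, 300)
        out = m.tker_evolution(model, t)
        assert np.all(np.diff(out) <= 0.0)
        assert np.all(out >= model.asymptote_ev)

    def test_evaluation_before_onset_is_refused_or_masked(self):
        model = m.IonDipoleModel()
        with pytest.raises(PreconditionError):
            m.tker_evolution(model, [40.0])
        out = m.tker_evolution(model, [40.0, 60.0], masked=True)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestIonDipoleFit:
    def test_noiseless_curve_is_recovered_exactly(self, truth):
        d, y, s = m.generate_mean_tker_curve(truth, noise_frac=0.0, seed=0)
        res = m.fit_ion_dipole(d, y, np.maximum(s, 1e-9))
        p = res.params
        assert p.v_m_per_s == pytest.approx(12.0, rel=1e-3)
        assert p.e_a_ev == pytest.approx(4.57, rel=1e-3)
        assert p.r_eq_pm == pytest.approx(490.0, rel=1e-3)

    def test_offset_start_recovers_identifiable_quantities(self, truth):
        """From a perturbed start the fit must land on the same curve:
        E_a and the predicted release are identifiable even though
        R_eq/theta/t_d individually are not."""
        d, y, s = m.generate_mean_tker_curve(truth, noise_frac=0.0, seed=0)
        init = m.IonDipoleModel(
            r_eq_pm=430.0, v_m_per_s=9.0, t_d_ps=46.0, theta_deg=45.0, e_a_ev=4.50
        )
        res = m.fit_ion_dipole(d, y, np.maximum(s, 1e-9), init=init)
        assert res.params.e_a_ev == pytest.approx(4.57, abs=1e-3)
        truth_curve = m.tker_evolution(truth.ion_dipole, d)
        np.testing.assert_allclose(res.predict(d), truth_curve, atol=1e-6)

    def test_reports_parameter_correlations(self, truth):
        d, y, s = m.generate_mean_tker_curve(truth, seed=0)
        res = m.fit_ion_dipole(d, y, s)
        assert ("r_eq_pm", "theta_deg") in res.correlations
        assert "V(R_eq, theta)" in res.summary()

    def test_too_few_delay_points_are_rejected(self):
        with pytest.raises(PreconditionError):
            m.IonDipoleTKERModel(np.arange(5), np.ones(5))
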