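"""Mechanistic simulator: equilibrium, calibration, cohorts, sessions, trials."""

import warnings

import numpy as np
import pytest

from citradose.circuit import balance_effluent
from citradose.domain import (
    ALBUMIN_5,
    FFP,
    CircuitSettings,
    PatientState,
    Prescription,
    Protocol,
)
from citradose.dosing import final_whole_blood_dose, fit_ratio_curve
from citradose.simulator import (
    ChelationParams,
    FinalProtocol,
    FixedDose,
    SimConfig,
    build_settings,
    calibrate_chelation,
    calibration_curve,
    circuit_equilibrium,
    generate_cohort,
    generate_dose_response_points,
    implied_ratio_curve,
    pci_required,
    run_virtual_trial,
    simulate_session,
)


class TestCircuitEquilibrium:
    def test_no_chelator_leaves_calcium_untouched(self, params):
        for c0 in (0.5, 1.0, 1.3):
            assert circuit_equilibrium(c0, 0.0, params) == pytest.approx(c0)

    def test_infinite_citrate_drives_calcium_to_zero(self, params):
        assert circuit_equilibrium(1.0, 1e6, params) == pytest.approx(0.0, abs=1e-5)

    def test_calibrated_anchor_case(self, params):
        assert circuit_equilibrium(1.0, 4.6, params) == pytest.approx(0.285, abs=1e-9)

    def test_agrees_with_brute_force_grid_search(self, params, rng):
        for _ in range(100):
            c0 = rng.uniform(0.4, 1.4)
            pci = rng.uniform(0.0, 8.0)
            sens = rng.uniform(0.7, 1.4)
            x = circuit_equilibrium(c0, pci, params, sens)
            grid = np.arange(1e-6, c0 + 1e-6, 1e-6)
            bm = sens * params.beta(c0)
            resid = np.abs(bm * (c0 - grid) * (params.kd + grid) - pci * grid)
            assert abs(x - grid[np.argmin(resid)]) < 1e-5

    def test_monotone_in_citrate_and_calcium(self, params):
        doses = np.linspace(0, 8, 30)
        out = [circuit_equilibrium(1.0, d, params) for d in doses]
        assert all(a > b for a, b in zip(out, out[1:]))
        calcium = np.linspace(0.5, 1.4, 30)
        out = [circuit_equilibrium(c, 4.0, params) for c in calcium]
        assert all(a < b for a, b in zip(out, out[1:]))

    def test_required_dose_inverts_the_equilibrium(self, params):
        for c0 in (0.6, 1.0, 1.3):
            pci = pci_required(c0, params, 0.30)
            assert circuit_equilibrium(c0, pci, params) == pytest.approx(0.30, abs=1e-12)


class TestCalibration:
    def test_requirement_falls_with_pretreatment_calcium(self, params):
        q = implied_ratio_curve(params).ratio
        assert q(0.85) > q(1.25)

    def test_flat_buffer_factor_gives_constant_ratio(self):
        p = ChelationParams(kd=0.5, beta0=2.0, beta1=0.0, beta2=0.0)
        q = implied_ratio_curve(p).ratio
        assert q(0.85) == pytest.approx(q(1.25))

    def test_infeasible_knots_raise_with_diagnostics(self):
        with pytest.raises(ValueError, match="calibration failed"):
            calibrate_chelation(knots=(0.30, 0.31))

    def test_calibration_set_refit_is_exact(self, params, cal_curve):
        exact = implied_ratio_curve(params)
        assert cal_curve.coefficients == pytest.approx(exact.coefficients, abs=1e-9)


class TestCohortGeneration:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=7)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_size_and_ranges(self):
        cfg = SimConfig(n_patients=47, seed=3, ht_range=(0.25, 0.40))
        cohort = generate_cohort(cfg)
        assert len(cohort) == 47
        assert all(0.25 <= p.hematocrit <= 0.40 for p in cohort)
        assert all(0.6 <= p.pcai0 <= 1.5 for p in cohort)
        assert all(p.sensitivity > 0 for p in cohort)

    def test_sensitivity_spread_tracks_noise_setting(self):
        wide = generate_cohort(SimConfig(n_patients=200, seed=5, response_noise_sd=0.2))
        narrow = generate_cohort(SimConfig(n_patients=200, seed=5, response_noise_sd=0.05))
        assert np.std([np.log(p.sensitivity) for p in wide]) > np.std(
            [np.log(p.sensitivity) for p in narrow]
        )


class TestSimulateSession:
    def _null_session(self, sim_config, duration=105.0):
        pat = PatientState(patient_id="n", hematocrit=0.3, pcai0=1.1, hco3_0=24.0)
        presc = Prescription(wbci=0, pci=0, citrate_pump=0, protocol=Protocol.FIXED)
        settings = balance_effluent(
            CircuitSettings(q_blood=200, q_substitution=40, q_citrate=0, q_calcium=0)
        )
        return simulate_session(pat, presc, settings, sim_config, duration)

    def test_null_intervention_leaves_chemistry_flat(self, sim_config):
        rec = self._null_session(sim_config)
        assert all(m.pcai == pytest.approx(1.1) for m in rec.measurements)
        assert all(m.hco3 == pytest.approx(24.0) for m in rec.measurements)
        # without any citrate the circuit is unanticoagulated: the clotting
        # proxy must engage even though the chemistry stays flat
        assert rec.measurements[-1].tmp > sim_config.tmp_baseline

    def test_unbalanced_settings_rejected(self, sim_config, patient):
        presc = Prescription(wbci=0, pci=0, citrate_pump=0)
        bad = CircuitSettings(q_blood=200, q_substitution=40, q_effluent=10)
        with pytest.raises(ValueError, match="unbalanced"):
            simulate_session(patient, presc, bad, sim_config)

    def test_closed_loop_final_protocol_hits_the_anchor(self, sim_config, cal_curve):
        for c0 in np.linspace(0.4, 1.4, 21):
            pat = PatientState(patient_id="c", hematocrit=0.32, pcai0=float(c0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                presc = final_whole_blood_dose(pat, cal_curve)
            settings = build_settings(presc, sim_config)
            rec = simulate_session(pat, presc, settings, sim_config, duration=10)
            assert rec.ccai_t5 == pytest.approx(0.285, abs=1e-6)
            assert all(m.tmp == sim_config.tmp_baseline for m in rec.measurements)

    def test_fixed_underdosing_reproduces_discovery_phase_failure(self, sim_config):
        # the discovery sessions dosed 2.4 mmol/L whole blood at high Ht and
        # saw circuit calcium ~0.40 with TMP elevation
        pat = PatientState(patient_id="A1", hematocrit=0.40, pcai0=1.14)
        wbci = 2.4
        presc = Prescription(
            wbci=wbci, pci=wbci / 0.6, citrate_pump=wbci * 200 / 113,
            protocol=Protocol.FIXED,
        )
        settings = build_settings(presc, sim_config)
        rec = simulate_session(pat, presc, settings, sim_config, duration=105)
        assert rec.ccai_t5 > 0.33
        assert rec.measurements[-1].tmp > sim_config.tmp_baseline

    def test_calcium_mass_balance_closes(self, sim_config, cal_curve, patient):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            presc = final_whole_blood_dose(patient, cal_curve)
        settings = build_settings(
            presc, sim_config, replacement_mix=((FFP, 0.6), (ALBUMIN_5, 0.4))
        )
        rec = simulate_session(patient, presc, settings, sim_config, duration=105)
        assert abs(rec.diagnostics["calcium_mass_balance_mmol"]) < 1e-6

    def test_sessions_reproducible_bit_identically(self, sim_config, cal_curve, patient):
        presc = final_whole_blood_dose(patient, cal_curve)
        settings = build_settings(presc, sim_config)
        a = simulate_session(patient, presc, settings, sim_config, duration=105)
        b = simulate_session(patient, presc, settings, sim_config, duration=105)
        assert a.model_dump() == b.model_dump()

    def test_citrate_load_raises_bicarbonate_and_total_calcium(self, sim_config, cal_curve, patient):
        presc = final_whole_blood_dose(patient, cal_curve)
        settings = build_settings(
            presc, sim_config, replacement_mix=((FFP, 0.8), (ALBUMIN_5, 0.2))
        )
        rec = simulate_session(patient, presc, settings, sim_config, duration=105)
        first, last = rec.measurements[0], rec.measurements[-1]
        assert last.hco3 > first.hco3
        assert last.pca_total > first.pca_total
        assert last.ph > first.ph - 1e-9


class TestParameterRecovery:
    def test_refit_from_simulated_sessions_reproduces_required_dose(self, params):
        # dose the *preliminary* protocol (not the titrated anchor dose), keep
        # in-window sessions only, and refit: the rebuilt cubic must match the
        # mechanism's requirement within 1% over the cohort range
        from citradose.dosing import DoseResponsePoint

        grid = np.linspace(0.85, 1.25, 30)
        pts = [
            DoseResponsePoint(float(c0), 4.6 * c0, circuit_equilibrium(c0, 4.6 * c0, params))
            for c0 in grid
        ]
        curve = fit_ratio_curve(pts)
        for c0 in np.linspace(0.85, 1.25, 17):
            rebuilt = float(curve.ratio(c0)) * (c0 - curve.anchor_ccai)
            truth = pci_required(c0, params)
            assert rebuilt == pytest.approx(truth, rel=0.01)


class TestVirtualTrial:
    def test_noise_free_final_protocol_is_always_in_window(self, params, cal_curve):
        cfg = SimConfig(n_patients=12, seed=11, response_noise_sd=0.0, params=params)
        cohort = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = run_virtual_trial(cohort, FinalProtocol(cal_curve), cfg, duration=30)
        assert summary.in_window == summary.n_sessions

    def test_individualized_dosing_beats_fixed_dosing(self, params, cal_curve):
        cfg = SimConfig(n_patients=38, seed=1, response_noise_sd=0.10, params=params)
        cohort = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixed = run_virtual_trial(cohort, FixedDose(3.6), cfg, duration=30)
            final = run_virtual_trial(cohort, FinalProtocol(cal_curve), cfg, duration=30)
        assert final.in_window >= fixed.in_window

    def test_bicarbonate_rise_monotone_in_ffp_fraction(self, params, cal_curve):
        cfg = SimConfig(n_patients=8, seed=2, response_noise_sd=0.0, params=params)
        cohort = generate_cohort(cfg)
        rises = []
        for frac in (0.0, 0.4, 0.8):
            mix = ((FFP, frac), (ALBUMIN_5, 1 - frac)) if frac else ((ALBUMIN_5, 1.0),)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = run_virtual_trial(
                    cohort, FinalProtocol(cal_curve), cfg, replacement_mix=mix
                )
            rises.append(s.mean_delta_hco3)
        assert rises[0] < rises[1] < rises[2]


class TestNoisyGeneration:
    def test_noisy_fit_keeps_good_explanatory_power(self, params):
        rng = np.random.default_rng(0)
        pts = generate_dose_response_points(
            params, np.linspace(0.8, 1.3, 30), noise_sd=0.10, rng=rng
        )
        curve = fit_ratio_curve(pts)
        assert curve.fit_r2 > 0.5

    def test_noisy_fit_still_decreasing_on_central_domain(self, params):
        rng = np.random.default_rng(0)
        pts = generate_dose_response_points(
            params, np.linspace(0.8, 1.3, 30), noise_sd=0.10, rng=rng
        )
        curve = fit_ratio_curve(pts)
        g = np.linspace(0.85, 1.25, 101)
        assert np.all(np.diff(curve.ratio(g)) < 0)

    def test_noisy_generation_requires_rng(self, params):
        with pytest.raises(ValueError, match="rng"):
            generate_dose_response_points(params, [1.0], noise_sd=0.1)
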