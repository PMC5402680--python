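"""Compartment model assembly, integration, steady state, mass balance."""

import numpy as np
import pytest

from neuropk import (
    BbbCalibration,
    CompartmentModel,
    ConfigurationError,
    DisruptionEvent,
    InvalidInputError,
    RenalParams,
    SourceOrgan,
    analytic_steady_state,
    build_model,
    detect_steady_state,
    get_biomarker,
    get_preset,
    mass_balance,
    simulate,
)
from neuropk.kinetics import REFERENCE_BRAIN_VOLUME, SimulationResult


def toy_model(
    brain_cl_max=20.0,
    brain_leak=2.5,
    renal_cl=90.0,
    blood_l=6.0,
    brain_conc=10.0,
    events=(),
    bidirectional=True,
    organs_extra=(),
):
    subject = get_preset("adult_male")
    subject = type(subject)(**{**subject.__dict__, "blood_volume": blood_l})
    organs = (
        SourceOrgan("brain", 1.42, brain_conc, brain_cl_max, brain_leak),
        *organs_extra,
    )
    cf = 0.872
    return CompartmentModel(
        subject=subject,
        biomarker=get_biomarker("s100b_monomer"),
        organs=organs,
        renal=RenalParams(gfr=renal_cl / cf, filtration_coefficient=cf, renal_clearance=renal_cl),
        events=tuple(events),
        bidirectional=bidirectional,
    )


class TestBuildModel:
    def test_adult_defaults(self, adult_male, s100b, calibration):
        model = build_model(adult_male, s100b, calibration)
        brain = model.brain
        assert brain.max_transfer_clearance == pytest.approx(
            calibration.max_transfer_clearance
        )
        assert brain.leak_fraction == 2.5
        assert brain.tissue_conc == 10.0
        assert model.renal.renal_clearance == pytest.approx(89.6, rel=5e-3)

    def test_neonate_volume_scaling(self, neonate, s100b, calibration):
        model = build_model(neonate, s100b, calibration)
        expected = calibration.max_transfer_clearance * 0.42 / REFERENCE_BRAIN_VOLUME
        assert model.brain.max_transfer_clearance == pytest.approx(expected)
        assert model.brain.leak_fraction == 10.0

    def test_skin_volume_scaling_and_leak(self, s100b, calibration):
        model = build_model(get_preset("light_skin"), s100b, calibration, include_skin=True)
        skin = next(o for o in model.organs if o.name == "skin")
        assert skin.max_transfer_clearance == pytest.approx(
            calibration.max_transfer_clearance * 7.8 / REFERENCE_BRAIN_VOLUME
        )
        assert skin.leak_fraction == 2.0
        assert skin.tissue_conc == 0.288

    def test_neonate_with_skin_unsupported(self, neonate, s100b, calibration):
        with pytest.raises(ConfigurationError, match="skin"):
            build_model(neonate, s100b, calibration, include_skin=True)

    def test_missing_calibration_rejected(self, adult_male, s100b):
        with pytest.raises(ConfigurationError, match="[Cc]alibration"):
            build_model(adult_male, s100b, None)

    def test_zero_leak_model_is_elimination_only(self, adult_male, s100b, calibration):
        model = build_model(adult_male, s100b, calibration, brain_leak=0.0)
        assert analytic_steady_state(model) == 0.0

    def test_brain_organ_required_exactly_once(self):
        with pytest.raises(ConfigurationError, match="brain"):
            CompartmentModel(
                subject=get_preset("adult_male"),
                biomarker=get_biomarker("s100b_monomer"),
                organs=(SourceOrgan("skin", 7.8, 0.288, 100.0, 2.0),),
                renal=RenalParams(gfr=100.0, filtration_coefficient=0.9, renal_clearance=90.0),
            )


class TestSimulate:
    def test_rises_monotonically_from_zero_to_plateau(self):
        result = simulate(toy_model(), duration=720.0)
        assert result.serum_conc[0] == 0.0
        assert np.all(np.diff(result.serum_conc) >= -1e-12)
        assert result.steady_state_conc is not None

    def test_plateau_matches_analytic_oracle(self):
        model = toy_model()
        result = simulate(model, duration=1440.0)
        assert result.steady_state_conc == pytest.approx(
            analytic_steady_state(model), rel=1e-3
        )

    def test_unidirectional_variant_oracle(self):
        model = toy_model(bidirectional=False)
        result = simulate(model, duration=1440.0)
        assert result.steady_state_conc == pytest.approx(
            analytic_steady_state(model), rel=1e-3
        )

    def test_disruption_peak_increment_near_anchor(self, adult_male, s100b, calibration):
        model = build_model(adult_male, s100b, calibration)
        settled = simulate(model, duration=1440.0)
        onset = settled.steady_state_time + 60.0
        event = DisruptionEvent(onset=onset, peak_index=100.0, recovery_tau=calibration.recovery_tau)
        run = simulate(model.with_events([event]), duration=onset + 240.0)
        increment = run.serum_conc.max() - settled.steady_state_conc
        assert increment == pytest.approx(0.22, rel=0.02)

    def test_invalid_duration_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate(toy_model(), duration=0.0)


class TestAnalyticSteadyState:
    def test_closed_form_single_organ(self):
        model = toy_model(brain_cl_max=20.0, brain_leak=2.5, renal_cl=90.0)
        cl = 0.025 * 20.0
        assert analytic_steady_state(model) == pytest.approx(cl * 10.0 / (cl + 90.0))

    def test_no_renal_elimination_equilibrates_with_source(self):
        model = toy_model(renal_cl=0.0)
        assert analytic_steady_state(model) == pytest.approx(10.0)

    def test_huge_renal_clearance_drives_to_zero(self):
        model = toy_model(renal_cl=1e9)
        assert analytic_steady_state(model) == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_clearances_undefined(self):
        model = toy_model(brain_cl_max=0.0, renal_cl=0.0)
        with pytest.raises(InvalidInputError, match="steady state"):
            analytic_steady_state(model)

    def test_event_model_rejected(self):
        model = toy_model(events=[DisruptionEvent(10.0, 100.0, 5.0)])
        with pytest.raises(InvalidInputError, match="event-free"):
            analytic_steady_state(model)

    def test_gliosis_raises_steady_state(self):
        # raising the brain source concentration strictly raises serum plateau
        levels = [analytic_steady_state(toy_model(brain_conc=b)) for b in (5.0, 10.0, 20.0)]
        assert levels[0] < levels[1] < levels[2]


class TestMassBalance:
    def test_event_free_run_conserves_mass(self):
        model = toy_model()
        result = simulate(model, duration=720.0)
        assert mass_balance(result, model) < 1e-6 * result.influx_mass[-1]

    def test_disruption_run_conserves_mass(self):
        model = toy_model(events=[DisruptionEvent(120.0, 100.0, 8.0)])
        result = simulate(model, duration=600.0)
        assert mass_balance(result, model) < 1e-6 * result.influx_mass[-1]

    def test_zero_leak_model_moves_no_mass(self):
        model = toy_model(brain_cl_max=0.0)
        result = simulate(model, duration=120.0)
        assert result.influx_mass[-1] == 0.0
        assert result.excreted_mass[-1] == 0.0
        assert np.all(result.serum_conc == 0.0)

    def test_excreted_mass_nondecreasing(self):
        model = toy_model(events=[DisruptionEvent(60.0, 100.0, 8.0)])
        result = simulate(model, duration=300.0)
        assert np.all(np.diff(result.excreted_mass) >= -1e-12)


class TestDetectSteadyState:
    def _result(self, t, c):
        z = np.zeros_like(t)
        return SimulationResult(times=t, serum_conc=c, excreted_mass=z, influx_mass=z, index=z)

    def test_constant_series_steady_at_window(self):
        t = np.arange(0.0, 200.0, 0.5)
        ss = detect_steady_state(self._result(t, np.full_like(t, 3.0)), window=60.0)
        assert ss is not None
        conc, time = ss
        assert conc == 3.0
        assert time == pytest.approx(60.0)

    def test_linear_growth_never_settles(self):
        t = np.arange(0.0, 500.0, 0.5)
        assert detect_steady_state(self._result(t, 0.01 * t), window=60.0) is None

    def test_settling_exponential_matches_oracle(self):
        model = toy_model()
        result = simulate(model, duration=1440.0)
        ss = detect_steady_state(result, rel_tol=1e-4, window=60.0)
        assert ss is not None
        assert ss[0] == pytest.approx(analytic_steady_state(model), rel=1e-3)


class TestDecayKinetics:
    def test_post_event_decay_matches_half_life_chain(self, adult_male, s100b, calibration):
        # after the barrier recloses, the increment decays with rate
        # (sum of baseline transfer clearances + renal clearance) / V_blood
        model = build_model(adult_male, s100b, calibration)
        c_ss = analytic_steady_state(model)
        onset = 0.0
        event = DisruptionEvent(onset, 100.0, calibration.recovery_tau)
        run = simulate(
            type(model)(**{**model.__dict__, "events": (event,), "initial_serum_conc": c_ss}),
            duration=600.0,
        )
        tail = (run.times > onset + 12 * calibration.recovery_tau) & (
            run.serum_conc - c_ss > 1e-4
        )
        t, inc = run.times[tail], run.serum_conc[tail] - c_ss
        rate = -np.polyfit(t, np.log(inc), 1)[0]
        expected = (model.brain.steady_clearance + model.renal.renal_clearance) / (
            model.blood_volume_ml
        )
        assert rate == pytest.approx(expected, rel=0.05)

    def test_higher_mw_marker_clears_more_slowly(self, adult_male, calibration):
        # same disruption, monomer vs homodimer: fitted decay constant ordering
        rates = {}
        for name in ("s100b_monomer", "s100b_dimer"):
            model = build_model(adult_male, get_biomarker(name), calibration)
            c_ss = analytic_steady_state(model)
            event = DisruptionEvent(0.0, 100.0, calibration.recovery_tau)
            run = simulate(
                type(model)(
                    **{**model.__dict__, "events": (event,), "initial_serum_conc": c_ss}
                ),
                duration=600.0,
            )
            tail = (run.times > 12 * calibration.recovery_tau) & (run.serum_conc - c_ss > 1e-4)
            rates[name] = -np.polyfit(
                run.times[tail], np.log(run.serum_conc[tail] - c_ss), 1
            )[0]
        assert rates["s100b_dimer"] < rates["s100b_monomer"]
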