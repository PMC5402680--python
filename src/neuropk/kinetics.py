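"""The compartment model: source organs, blood pool, renal sink.

A biomarker diffuses from fixed-concentration source organs (brain behind
the blood–brain barrier, optionally skin) into a single well-mixed blood
compartment, and is eliminated by glomerular filtration:

    V_blood · dC/dt = Σ_i CL_i(t)·(B_i − C) − CL_renal·C

where B_i is organ i's (constant) tissue concentration and CL_i(t) its
transfer clearance — the organ's maximal clearance scaled by the current
radiologic index (brain) or a fixed leak fraction (extracranial organs).
Exchange is gradient-driven and bidirectional by default; a unidirectional
influx variant (CL_i·B_i, no back-flux) is available as a toggle. Since
B_i ≫ C in all default scenarios the two differ by well under 1%.

The module also provides the algebraic steady state (an independent oracle
for the integrator), cumulative mass accounting for conservation checks, and
plateau detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import bbb, physiology
from .bbb import BbbCalibration, DisruptionEvent
from .errors import ConfigurationError, InvalidInputError, IntegrationError
from .physiology import Biomarker, RenalParams, SubjectProfile

#: Adult reference brain volume (liters) to which the calibrated maximal
#: clearance refers; organ maxima scale by volume relative to it.
REFERENCE_BRAIN_VOLUME = 1.42

#: Skin leak fraction, percent of maximal (steady tissue-to-blood transfer).
SKIN_LEAK = 2.0

#: Solver tolerances and output grid default.
RTOL = 1e-8
ATOL = 1e-12  # ng/ml
DEFAULT_DT = 0.5  # minutes

#: Negative-concentration clip tolerance (solver undershoot), ng/ml.
NEGATIVE_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class SourceOrgan:
    """A fixed-concentration tissue exchanging marker with blood."""

    name: str
    volume: float  # liters
    tissue_conc: float  # ng/ml, held constant
    max_transfer_clearance: float  # ml/min at index/leak 100
    leak_fraction: float  # percent of maximum at baseline

    def __post_init__(self):
        if not self.volume > 0:
            raise InvalidInputError(f"organ {self.name}: volume must be > 0")
        if self.tissue_conc < 0:
            raise InvalidInputError(f"organ {self.name}: tissue_conc must be >= 0")
        if self.max_transfer_clearance < 0:
            raise InvalidInputError(f"organ {self.name}: max_transfer_clearance must be >= 0")
        if not 0.0 <= self.leak_fraction <= 100.0:
            raise InvalidInputError(f"organ {self.name}: leak_fraction must lie in [0,100]")

    @property
    def steady_clearance(self) -> float:
        """Transfer clearance (ml/min) at the baseline leak."""
        return self.leak_fraction / 100.0 * self.max_transfer_clearance


@dataclass(frozen=True)
class CompartmentModel:
    """Assembled ODE system for one subject/biomarker pair."""

    subject: SubjectProfile
    biomarker: Biomarker
    organs: tuple[SourceOrgan, ...]
    renal: RenalParams
    events: tuple[DisruptionEvent, ...] = ()
    initial_serum_conc: float = 0.0  # ng/ml
    bidirectional: bool = True

    def __post_init__(self):
        brains = [o for o in self.organs if o.name == "brain"]
        if len(brains) != 1:
            raise ConfigurationError("model requires exactly one brain organ")
        if self.initial_serum_conc < 0:
            raise InvalidInputError("initial_serum_conc must be >= 0")

    @property
    def brain(self) -> SourceOrgan:
        return next(o for o in self.organs if o.name == "brain")

    @property
    def blood_volume_ml(self) -> float:
        return self.subject.blood_volume * 1000.0

    def with_events(self, events: Sequence[DisruptionEvent]) -> "CompartmentModel":
        return replace(self, events=tuple(events))


@dataclass
class SimulationResult:
    """Time grid with serum concentration, mass ledgers, and diagnostics."""

    times: np.ndarray  # minutes
    serum_conc: np.ndarray  # ng/ml
    excreted_mass: np.ndarray  # ng, cumulative
    influx_mass: np.ndarray  # ng, cumulative net organ-to-blood
    index: np.ndarray  # radiologic index of the brain barrier
    steady_state_conc: float | None = None  # ng/ml
    steady_state_time: float | None = None  # minutes


def build_model(
    subject: SubjectProfile,
    biomarker: Biomarker,
    calibration: BbbCalibration,
    include_skin: bool = False,
    events: Sequence[DisruptionEvent] = (),
    brain_leak: float | None = None,
    bidirectional: bool = True,
) -> CompartmentModel:
    """Assemble a compartment model from a subject, a marker, and the
    calibrated barrier constants.

    The brain's maximal clearance is the calibrated adult reference scaled
    by brain volume; its baseline leak defaults by age class (2.5% adult,
    10% newborn). The optional skin organ (adult males only) transfers at
    2% of a maximum scaled by the skin/brain volume ratio, with tissue
    concentration taken from the subject's pigmentation-dependent skin
    S100B level. Renal clearance is GFR × C_F(MW).
    """
    if calibration is None:
        raise ConfigurationError("a BbbCalibration is required to build a model")
    if brain_leak is None:
        brain_leak = (
            bbb.NEWBORN_BASELINE_LEAK
            if subject.age_class == "neonate"
            else bbb.ADULT_BASELINE_LEAK
        )
    scale = subject.brain_volume / REFERENCE_BRAIN_VOLUME
    organs = [
        SourceOrgan(
            name="brain",
            volume=subject.brain_volume,
            tissue_conc=biomarker.brain_conc,
            max_transfer_clearance=calibration.max_transfer_clearance * scale,
            leak_fraction=brain_leak,
        )
    ]
    if include_skin:
        if subject.age_class == "neonate":
            raise ConfigurationError(
                "skin compartment is modeled for adults only; neonate profiles do not support it"
            )
        organs.append(
            SourceOrgan(
                name="skin",
                volume=subject.skin_volume,
                tissue_conc=subject.skin_marker_conc,
                max_transfer_clearance=calibration.max_transfer_clearance
                * (subject.skin_volume / REFERENCE_BRAIN_VOLUME),
                leak_fraction=SKIN_LEAK,
            )
        )
    return CompartmentModel(
        subject=subject,
        biomarker=biomarker,
        organs=tuple(organs),
        renal=physiology.renal_params_for(subject, biomarker),
        events=tuple(events),
        bidirectional=bidirectional,
    )


def _brain_index(model: CompartmentModel, t):
    return bbb.index_profile(t, model.brain.leak_fraction, model.events)


def _clearances(model: CompartmentModel, t: float) -> list[float]:
    """Instantaneous transfer clearances (ml/min), brain first."""
    cls = []
    for organ in model.organs:
        if organ.name == "brain":
            idx = _brain_index(model, t)
            cls.append(
                float(
                    bbb.transfer_clearance_from_index(idx, organ.max_transfer_clearance)
                )
                if organ.max_transfer_clearance > 0
                else 0.0
            )
        else:
            cls.append(organ.steady_clearance)
    return cls


def simulate(
    model: CompartmentModel,
    duration: float,
    dt: float = DEFAULT_DT,
    rel_tol: float = 1e-4,
    window: float = 60.0,
) -> SimulationResult:
    """Integrate the blood-pool ODE over ``duration`` minutes.

    State is (serum concentration, cumulative net influx mass, cumulative
    excreted mass); output is sampled on a fixed grid of step ``dt``. The
    integration is segmented at event onsets so the index discontinuities
    never cross a solver step. Steady-state diagnostics use
    :func:`detect_steady_state` with (``rel_tol``, ``window``).
    """
    if not duration > 0:
        raise InvalidInputError("duration must be > 0")
    if not dt > 0:
        raise InvalidInputError("dt must be > 0")

    v_blood = model.blood_volume_ml
    concs = [o.tissue_conc for o in model.organs]

    def rhs(t, y):
        c = y[0]
        cls = _clearances(model, t)
        if model.bidirectional:
            influx = sum(cl * (b - c) for cl, b in zip(cls, concs))
        else:
            influx = sum(cl * b for cl, b in zip(cls, concs))
        excretion = model.renal.renal_clearance * c
        return [(influx - excretion) / v_blood, influx, excretion]

    t_grid = np.arange(0.0, duration + dt / 2.0, dt)
    breakpoints = sorted({ev.onset for ev in model.events if 0.0 < ev.onset < duration})
    segments = [0.0, *breakpoints, float(duration)]

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    y0 = [model.initial_serum_conc, 0.0, 0.0]
    for left, right in zip(segments[:-1], segments[1:]):
        mask = (t_grid >= left) & (t_grid <= right)
        t_eval = np.unique(np.concatenate(([left], t_grid[mask], [right])))
        sol = solve_ivp(
            rhs, (left, right), y0, t_eval=t_eval, method="LSODA", rtol=RTOL, atol=ATOL
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{left}, {right}] min: {sol.message}")
        keep = np.isin(sol.t, t_grid[mask])
        times.append(sol.t[keep])
        states.append(sol.y[:, keep])
        y0 = sol.y[:, -1]

    t_out = np.concatenate(times)
    y_out = np.concatenate(states, axis=1)
    # De-duplicate grid points shared by adjacent segments.
    t_out, unique_idx = np.unique(t_out, return_index=True)
    y_out = y_out[:, unique_idx]

    serum = y_out[0]
    if serum.min() < -NEGATIVE_CLIP_TOL:
        raise IntegrationError(
            f"negative serum concentration beyond tolerance: min {serum.min():.3e} ng/ml"
        )
    serum = np.maximum(serum, 0.0)

    result = SimulationResult(
        times=t_out,
        serum_conc=serum,
        influx_mass=y_out[1],
        excreted_mass=y_out[2],
        index=np.asarray(_brain_index(model, t_out), dtype=float),
    )
    ss = detect_steady_state(result, rel_tol=rel_tol, window=window)
    if ss is not None:
        result.steady_state_conc, result.steady_state_time = ss
    return result


def analytic_steady_state(model: CompartmentModel) -> float:
    """Closed-form steady-state serum concentration for an event-free model.

    Bidirectional exchange gives C* = Σ CL_i·B_i / (Σ CL_i + CL_renal) with
    CL_i the baseline transfer clearances; the unidirectional variant gives
    Σ CL_i·B_i / CL_renal. An independent algebraic oracle for the solver.
    """
    if model.events:
        raise InvalidInputError("analytic_steady_state requires an event-free model")
    cls = [o.steady_clearance for o in model.organs]
    total_in = sum(cl * o.tissue_conc for cl, o in zip(cls, model.organs))
    if model.bidirectional:
        denom = sum(cls) + model.renal.renal_clearance
    else:
        denom = model.renal.renal_clearance
    if denom == 0.0:
        raise InvalidInputError("steady state undefined: all clearances are zero")
    return total_in / denom


def mass_balance(result: SimulationResult, model: CompartmentModel) -> float:
    """Absolute conservation discrepancy in ng over the whole run:

    |cumulative influx − cumulative excretion − blood-pool content change|.
    """
    content_change = (result.serum_conc[-1] - result.serum_conc[0]) * model.blood_volume_ml
    return abs(result.influx_mass[-1] - result.excreted_mass[-1] - content_change)


def detect_steady_state(
    result: SimulationResult, rel_tol: float = 1e-4, window: float = 60.0
) -> tuple[float, float] | None:
    """Earliest time at which the serum concentration has settled.

    Returns (concentration, time) at the first grid point whose trailing
    ``window`` minutes vary by less than ``rel_tol`` relative to the local
    level, or None if the series never settles.
    """
    t = result.times
    c = result.serum_conc
    if t.size == 0:
        return None
    for k in range(t.size):
        if t[k] - t[0] < window:
            continue
        seg = c[(t >= t[k] - window) & (t <= t[k])]
        level = max(abs(seg).max(), ATOL)
        if (seg.max() - seg.min()) / level < rel_tol:
            return float(c[k]), float(t[k])
    return None
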