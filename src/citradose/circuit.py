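"""Flow balance of the Ci-Ca plasma-exchange circuit.

The Ci-Ca module slaves the citrate pump to the blood pump (fixed citrate
concentration per litre of whole blood regardless of blood flow) and the
effluent pump to the sum of the substitution, citrate and calcium pumps, so
the net fluid balance of the circuit is zero by construction. Citrate (and,
in this model, nothing else) enters the filter inflow as predilution; the
calcium line returns post-filter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .domain import CircuitSettings, PatientState, Solution

__all__ = [
    "FFConvention",
    "FlowBalance",
    "plasma_flow",
    "citrate_pump_rate",
    "balance_effluent",
    "flow_balance",
    "filtration_fraction",
    "exchange_volumes",
    "single_pass_citrate_removal",
]


class FFConvention(str, enum.Enum):
    """Which denominator defines the filtration fraction.

    ``SUBSTITUTION_OVER_PATIENT_PLASMA`` divides the substitution rate by the
    patient-derived plasma flow and reproduces the study's headline 25-32%
    range over its hematocrit span. ``FILTRATE_OVER_INFLOW`` divides the
    effluent rate by the full filter inflow (plasma plus citrate predilution)
    and is the physically complete definition; it is strictly smaller whenever
    predilution is running and no calcium is being returned.
    """

    SUBSTITUTION_OVER_PATIENT_PLASMA = "substitution_over_patient_plasma"
    FILTRATE_OVER_INFLOW = "filtrate_over_inflow"


@dataclass(frozen=True)
class FlowBalance:
    """Derived flow quantities of a circuit configuration, all in mL/min."""

    q_plasma_patient: float
    q_plasma_inflow: float
    q_filtrate: float
    filtration_fraction: float
    net_fluid_balance: float


def plasma_flow(q_blood: float, hematocrit: float) -> float:
    """Plasma flow derived from blood flow: ``q_blood * (1 - Ht)`` (mL/min)."""
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError(f"hematocrit: {hematocrit!r} must lie in [0, 1)")
    if q_blood < 0:
        raise ValueError("q_blood: must be non-negative")
    return q_blood * (1.0 - hematocrit)


def citrate_pump_rate(wbci: float, q_blood: float, anticoagulant: Solution) -> float:
    """Citrate pump rate delivering ``wbci`` mmol citrate per litre of blood.

    The Ci-Ca citrate pump is slaved to the blood pump; the rate that realizes
    a whole-blood citrate concentration ``wbci`` with an anticoagulant of
    concentration ``c`` mmol/L is ``wbci * q_blood / c`` (mL/min).
    """
    if wbci < 0:
        raise ValueError("wbci: must be non-negative")
    if anticoagulant.citrate_conc <= 0:
        raise ValueError(
            "anticoagulant.citrate_conc: must be positive (dilution undefined)"
        )
    return wbci * q_blood / anticoagulant.citrate_conc


def balance_effluent(settings: CircuitSettings) -> CircuitSettings:
    """Return settings with the effluent pump slaved to the other three pumps.

    The effluent rate is set to ``q_substitution + q_citrate + q_calcium`` so
    the circuit runs at neutral fluid balance.
    """
    q_eff = settings.q_substitution + settings.q_citrate + settings.q_calcium
    return settings.model_copy(update={"q_effluent": q_eff})


def flow_balance(
    settings: CircuitSettings,
    patient: PatientState,
    convention: FFConvention = FFConvention.SUBSTITUTION_OVER_PATIENT_PLASMA,
) -> FlowBalance:
    """Compute the derived flow quantities for a circuit/patient pair."""
    q_pp = plasma_flow(settings.q_blood, patient.hematocrit)
    q_in = q_pp + settings.q_citrate
    net = (
        settings.q_substitution
        + settings.q_citrate
        + settings.q_calcium
        - settings.q_effluent
    )
    return FlowBalance(
        q_plasma_patient=q_pp,
        q_plasma_inflow=q_in,
        q_filtrate=settings.q_effluent,
        filtration_fraction=filtration_fraction(settings, patient, convention),
        net_fluid_balance=net,
    )


def filtration_fraction(
    settings: CircuitSettings,
    patient: PatientState,
    convention: FFConvention = FFConvention.SUBSTITUTION_OVER_PATIENT_PLASMA,
) -> float:
    """Filtration fraction of the plasmafilter under the chosen convention."""
    q_pp = plasma_flow(settings.q_blood, patient.hematocrit)
    if convention is FFConvention.SUBSTITUTION_OVER_PATIENT_PLASMA:
        if q_pp <= 0:
            raise ValueError("plasma flow is zero; filtration fraction undefined")
        ff = settings.q_substitution / q_pp
    else:
        q_in = q_pp + settings.q_citrate
        if q_in <= 0:
            raise ValueError("filter inflow is zero; filtration fraction undefined")
        ff = settings.q_effluent / q_in
    if not 0.0 <= ff < 1.0:
        raise ValueError(
            f"filtration fraction {ff:.3f} outside [0, 1); flows are inconsistent"
        )
    return ff


def exchange_volumes(
    settings: CircuitSettings, duration: float
) -> tuple[float, float, float]:
    """Exchange-volume bookkeeping over a session.

    Returns ``(prescribed_exchange, total_exchange, predilution_volume)`` in
    litres. The prescribed exchange is what the substitution pump replaces;
    the citrate and calcium lines add a predilution volume that the slaved
    effluent pump compensates by extra plasma filtration, so the total
    exchanged volume exceeds the prescription.
    """
    if duration <= 0:
        raise ValueError("duration: must be positive")
    prescribed = settings.q_substitution * duration / 1000.0
    predilution = (settings.q_citrate + settings.q_calcium) * duration / 1000.0
    return prescribed, prescribed + predilution, predilution


def single_pass_citrate_removal(
    settings: CircuitSettings, patient: PatientState, sieving: float = 1.0
) -> float:
    """Fraction of pre-filter citrate leaving in the effluent per pass.

    Citrate is a small solute removed convectively; with a sieving
    coefficient ``s`` the single-pass removal is
    ``s * q_effluent / (plasma flow + q_citrate)``. At typical settings this
    stays below about 0.30 — the reason RCA for plasma exchange carries a
    systemic citrate load (hemodialysis clears far more by diffusion).
    """
    if not 0.0 <= sieving <= 1.0:
        raise ValueError("sieving: must lie in [0, 1]")
    q_in = plasma_flow(settings.q_blood, patient.hematocrit) + settings.q_citrate
    if q_in <= 0:
        raise ValueError("filter inflow is zero; removal fraction undefined")
    return sieving * settings.q_effluent / q_in
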