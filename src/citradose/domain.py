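"""Shared domain types and unit conventions for Ci-Ca TPE modelling.

Unit conventions used throughout the package:

* concentrations in mmol/L,
* pump flows in mL/min (the CLI converts mL/h on input/output),
* hematocrit as a volume fraction in (0, 0.65),
* time in minutes from session start,
* transmembrane pressure (TMP) in mmHg.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "normalize_hematocrit",
    "PatientState",
    "Solution",
    "CircuitSettings",
    "Measurement",
    "Prescription",
    "SafetyEvent",
    "SessionRecord",
    "Protocol",
    "EventKind",
    "ACD_A",
    "FFP",
    "ALBUMIN_5",
    "GELATIN",
    "CALCIUM_MAGNESIUM",
    "DEFAULT_TARGET_WINDOW",
]

#: Therapeutic window for circuit ionized calcium at 5 minutes, mmol/L.
DEFAULT_TARGET_WINDOW: tuple[float, float] = (0.24, 0.33)


def normalize_hematocrit(value: float) -> float:
    """Normalize a hematocrit given either as a fraction or as a percent.

    Values in (0, 0.65] are taken as fractions; values in (1, 65] are taken
    as percentages and divided by 100. Anything else is outside the
    physiological range and rejected.

    Parameters
    ----------
    value : float
        Hematocrit as a fraction (e.g. 0.27) or percent (e.g. 27).

    Returns
    -------
    float
        Hematocrit as a fraction in (0, 0.65].
    """
    v = float(value)
    if 0.0 < v <= 0.65:
        return v
    if 1.0 < v <= 65.0:
        return v / 100.0
    raise ValueError(
        f"hematocrit: value {value!r} is outside both the fractional (0, 0.65] "
        f"and the percent (1, 65] range"
    )


class Solution(BaseModel):
    """An infusion or replacement solution and its relevant composition.

    ``citrate_salt_fraction`` is the fraction of the solution's citrate that
    carries alkali potential (trisodium citrate); the citric-acid remainder
    brings three protons per molecule and yields no net bicarbonate on
    metabolism.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    citrate_conc: float = Field(0.0, ge=0.0, description="total citrate, mmol/L")
    citrate_salt_fraction: float = Field(1.0, ge=0.0, le=1.0)
    calcium_conc: float = Field(0.0, ge=0.0, description="total calcium, mmol/L")
    magnesium_to_calcium: float = Field(0.0, ge=0.0, description="molar ratio Mg:Ca")


#: ACD-A anticoagulant: 113 mmol/L total citrate, part of it as citric acid.
ACD_A = Solution(
    name="ACD-A", citrate_conc=113.0, citrate_salt_fraction=0.66, calcium_conc=0.0
)
#: Fresh frozen plasma as replacement fluid (citrate load 17-21 mmol/L; midpoint
#: used as default) with a donor-plasma calcium content.
FFP = Solution(
    name="FFP", citrate_conc=19.0, citrate_salt_fraction=1.0, calcium_conc=2.2
)
ALBUMIN_5 = Solution(name="albumin 5%", citrate_conc=0.0, calcium_conc=0.0)
GELATIN = Solution(name="gelatin", citrate_conc=0.0, calcium_conc=0.0)
#: Mixed calcium/magnesium chloride repletion solution, Mg:Ca molar ratio 0.36.
CALCIUM_MAGNESIUM = Solution(
    name="calcium-magnesium chloride",
    citrate_conc=0.0,
    calcium_conc=100.0,
    magnesium_to_calcium=0.36,
)


class PatientState(BaseModel):
    """Pre-treatment patient values that drive an RCA prescription."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    hematocrit: float = Field(..., gt=0.0, lt=0.65, description="fraction of blood volume")
    pcai0: float = Field(..., gt=0.0, description="pre-treatment ionized calcium, mmol/L")
    weight: Optional[float] = Field(None, gt=0.0, description="kg")
    pca_total0: Optional[float] = Field(None, gt=0.0, description="total calcium, mmol/L")
    hco3_0: Optional[float] = Field(None, gt=0.0, description="bicarbonate, mmol/L")
    ph0: Optional[float] = Field(None, gt=6.5, lt=8.0)

    @model_validator(mode="after")
    def _total_at_least_ionized(self) -> "PatientState":
        if self.pca_total0 is not None and self.pca_total0 < self.pcai0:
            raise ValueError("pca_total0: total calcium cannot be below ionized calcium")
        return self


class CircuitSettings(BaseModel):
    """Pump flows and solution compositions defining the extracorporeal circuit.

    The effluent pump of the Ci-Ca module is slaved to equalize the sum of the
    substitution, citrate and calcium pump rates (see
    :func:`citradose.circuit.balance_effluent`); ``q_effluent`` is therefore a
    derived quantity and is not validated at construction time.
    """

    model_config = ConfigDict(frozen=True)

    q_blood: float = Field(..., ge=0.0, description="mL/min")
    q_substitution: float = Field(..., ge=0.0, description="mL/min")
    q_citrate: float = Field(0.0, ge=0.0, description="mL/min")
    q_calcium: float = Field(0.0, ge=0.0, description="mL/min")
    q_effluent: float = Field(0.0, ge=0.0, description="mL/min")
    anticoagulant: Solution = ACD_A
    calcium_solution: Solution = CALCIUM_MAGNESIUM
    replacement_mix: tuple[tuple[Solution, float], ...] = ((ALBUMIN_5, 1.0),)

    @field_validator("replacement_mix")
    @classmethod
    def _fractions_sum_to_one(cls, mix):
        if mix:
            total = sum(frac for _, frac in mix)
            if any(frac < 0 for _, frac in mix) or abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"replacement_mix: volume fractions must be >= 0 and sum to 1 "
                    f"(got {total:.6f})"
                )
        return tuple(mix)

    def replacement_citrate_conc(self) -> float:
        """Volume-weighted citrate concentration of the replacement mix, mmol/L."""
        return sum(frac * sol.citrate_conc for sol, frac in self.replacement_mix)

    def replacement_calcium_conc(self) -> float:
        """Volume-weighted calcium concentration of the replacement mix, mmol/L."""
        return sum(frac * sol.calcium_conc for sol, frac in self.replacement_mix)

    def replacement_citrate_salt_fraction(self) -> float:
        """Citrate-weighted alkali-carrying fraction of the replacement citrate."""
        total = self.replacement_citrate_conc()
        if total <= 0:
            return 1.0
        return (
            sum(
                frac * sol.citrate_conc * sol.citrate_salt_fraction
                for sol, frac in self.replacement_mix
            )
            / total
        )


class Measurement(BaseModel):
    """A time-stamped set of bedside measurements during one session.

    All concentrations are optional: safety checks that need a missing value
    report "not evaluable" instead of failing.
    """

    model_config = ConfigDict(frozen=True)

    t: float = Field(..., ge=0.0, description="minutes from session start")
    pcai: Optional[float] = Field(None, ge=0.0, description="systemic iCa, mmol/L")
    ccai: Optional[float] = Field(None, ge=0.0, description="circuit iCa, mmol/L")
    pca_total: Optional[float] = Field(None, ge=0.0)
    hco3: Optional[float] = Field(None, ge=0.0)
    ph: Optional[float] = None
    tmp: Optional[float] = Field(None, ge=0.0, description="mmHg")
    symptoms: Optional[bool] = Field(
        None, description="hypocalcemia-related symptoms present (None = unknown)"
    )


class Protocol(str, enum.Enum):
    """Which dosing protocol issued a prescription."""

    FIXED = "fixed"
    PRELIMINARY = "preliminary"
    FINAL = "final"


class Prescription(BaseModel):
    """A citrate prescription: whole-blood and plasma dose plus pump rate."""

    model_config = ConfigDict(frozen=True)

    wbci: float = Field(..., ge=0.0, description="mmol citrate per L whole blood")
    pci: float = Field(..., ge=0.0, description="mmol citrate per L plasma")
    citrate_pump: float = Field(..., ge=0.0, description="mL/min")
    target_window: tuple[float, float] = DEFAULT_TARGET_WINDOW
    protocol: Protocol = Protocol.FINAL
    adapted: bool = False

    @field_validator("target_window")
    @classmethod
    def _window_ordered(cls, w):
        low, high = w
        if not low < high:
            raise ValueError("target_window: low bound must be below high bound")
        return (float(low), float(high))

    @property
    def anchor(self) -> float:
        """Midpoint of the target window, mmol/L."""
        low, high = self.target_window
        return 0.5 * (low + high)


class EventKind(str, enum.Enum):
    HYPOCALCEMIA = "hypocalcemia"
    CITRATE_ACCUMULATION = "citrate_accumulation"
    CLOTTING_THREAT = "clotting_threat"
    OVERDOSE = "overdose"
    UNDERDOSE = "underdose"
    TF = "tf"
    PTF = "ptf"
    NOT_EVALUABLE = "not_evaluable"


class SafetyEvent(BaseModel):
    """A tagged safety event detected at time ``t`` during a session."""

    model_config = ConfigDict(frozen=True)

    t: float = Field(..., ge=0.0)
    kind: EventKind
    value: Optional[float] = None
    action: str = ""


class SessionRecord(BaseModel):
    """One TPE treatment: inputs, measurements and detected events."""

    patient: PatientState
    settings: CircuitSettings
    prescription: Prescription
    measurements: list[Measurement]
    duration: float = Field(..., gt=0.0, description="minutes")
    events: list[SafetyEvent] = Field(default_factory=list)
    completed: bool = True
    diagnostics: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _measurements_sorted_within_duration(self) -> "SessionRecord":
        times = [m.t for m in self.measurements]
        if times != sorted(times):
            raise ValueError("measurements: must be sorted by time")
        if times and self.duration < times[-1]:
            raise ValueError("duration: must cover the last measurement time")
        return self

    def at(self, t: float) -> Optional[Measurement]:
        """Return the measurement taken at time ``t``, if any."""
        for m in self.measurements:
            if abs(m.t - t) < 1e-9:
                return m
        return None

    @property
    def ccai_t5(self) -> Optional[float]:
        m = self.at(5.0)
        return m.ccai if m is not None else None
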