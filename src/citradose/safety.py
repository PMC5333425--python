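"""Clinical safety layer: calcium titration, event detection, session audit.

Thresholds follow the clinical definitions: symptomatic hypocalcemia below
0.85 mmol/L systemic ionized calcium; citrate accumulation as a
total-to-ionized calcium ratio above 2.5; partial treatment failure (PTF) as
a TMP rise of more than 50 mmHg with the session still completed; treatment
failure (TF) as a session that cannot be completed; and a clotting threat
whenever the circuit ionized calcium reaches 0.35 mmol/L.

The calcium-supplementation band table is a *reconstructed* default: the
original supplementary step tables are not reproduced here, so the algorithm
slot is kept but its cells are configurable site policy rather than ground
truth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .domain import (
    EventKind,
    Measurement,
    SafetyEvent,
    SessionRecord,
)

__all__ = [
    "TitrationBand",
    "SafetyConfig",
    "SessionOutcome",
    "titrate_calcium",
    "accumulation_ratio",
    "classify_session",
    "audit_cohort",
    "lint_prescription",
]


@dataclass(frozen=True)
class TitrationBand:
    """One row of the calcium titration table: pcai in [low, high) -> step."""

    low: float
    high: float
    delta_q_calcium: float  # mL/min adjustment of the calcium pump
    label: str


#: Reconstructed default calcium-titration table (see module docstring).
DEFAULT_TITRATION_TABLE: tuple[TitrationBand, ...] = (
    TitrationBand(0.0, 0.85, +0.5, "hypocalcemia: large step up"),
    TitrationBand(0.85, 1.00, +0.2, "low-normal: small step up"),
    TitrationBand(1.00, 1.20, 0.0, "normocalcemic: no change"),
    TitrationBand(1.20, float("inf"), -0.2, "high: step down"),
)


@dataclass(frozen=True)
class SafetyConfig:
    """Thresholds and schedule of the monitoring layer."""

    hypocalcemia_threshold: float = 0.85  # mmol/L systemic ionized calcium
    accumulation_ratio_threshold: float = 2.5  # pCa total / pCai
    clotting_ccai_threshold: float = 0.35  # mmol/L circuit ionized calcium
    ptf_tmp_rise: float = 50.0  # mmHg
    schedule: tuple[float, ...] = (5.0, 30.0, 60.0, 90.0)
    calcium_titration_table: tuple[TitrationBand, ...] = DEFAULT_TITRATION_TABLE

    def __post_init__(self):
        if list(self.schedule) != sorted(self.schedule):
            raise ValueError("schedule: must be sorted ascending")
        bands = self.calcium_titration_table
        for a, b in zip(bands, bands[1:]):
            if abs(a.high - b.low) > 1e-12:
                raise ValueError("calcium_titration_table: bands must be contiguous")


def titrate_calcium(
    measurement: Measurement, config: SafetyConfig = SafetyConfig()
) -> tuple[float, list[SafetyEvent]]:
    """Calcium-pump adjustment (mL/min) for a systemic ionized calcium value.

    Applies the configured band table. A missing pcai yields a zero
    adjustment and a ``not_evaluable`` event rather than an error.
    """
    if measurement.pcai is None:
        return 0.0, [
            SafetyEvent(
                t=measurement.t,
                kind=EventKind.NOT_EVALUABLE,
                action="calcium titration skipped: pcai not measured",
            )
        ]
    pcai = measurement.pcai
    events: list[SafetyEvent] = []
    if pcai < config.hypocalcemia_threshold:
        subtype = "symptomatic" if measurement.symptoms else "biochemical"
        events.append(
            SafetyEvent(
                t=measurement.t,
                kind=EventKind.HYPOCALCEMIA,
                value=pcai,
                action=f"{subtype} hypocalcemia: increase calcium infusion",
            )
        )
    for band in config.calcium_titration_table:
        if band.low <= pcai < band.high:
            return band.delta_q_calcium, events
    return 0.0, events


def accumulation_ratio(pca_total: float, pcai: float, threshold: float = 2.5) -> tuple[float, bool]:
    """Total-to-ionized calcium ratio and the citrate-accumulation flag.

    The flag is set on a strictly greater-than comparison with the threshold;
    the ratio is an a-posteriori indicator and should be read together with
    ionized calcium and bicarbonate.
    """
    if pcai <= 0:
        raise ValueError("pcai: must be positive to form the ratio")
    ratio = pca_total / pcai
    return ratio, ratio > threshold


class SessionOutcome(str, enum.Enum):
    COMPLETED = "completed"
    PTF = "ptf"
    TF = "tf"
    NOT_EVALUABLE = "not_evaluable"


def classify_session(
    record: SessionRecord, config: SafetyConfig = SafetyConfig()
) -> tuple[SessionOutcome, list[SafetyEvent]]:
    """Classify a session as completed / PTF / TF and emit safety events.

    Early termination with a clotting course dominates TMP magnitude (TF);
    a completed session with a TMP rise strictly above the PTF threshold is a
    partial failure. Clotting-threat events are emitted at every measurement
    whose circuit calcium is at or above the clotting threshold, and
    citrate-accumulation / hypocalcemia events wherever the needed values are
    present. A session without any TMP values is not evaluable.
    """
    events: list[SafetyEvent] = []
    tmps = [m.tmp for m in record.measurements if m.tmp is not None]
    for m in record.measurements:
        if m.ccai is not None and m.ccai >= config.clotting_ccai_threshold:
            events.append(
                SafetyEvent(
                    t=m.t, kind=EventKind.CLOTTING_THREAT, value=m.ccai,
                    action="circuit calcium at/above clotting threshold; "
                    "increase citrate dose",
                )
            )
        if m.pcai is not None and m.pcai < config.hypocalcemia_threshold:
            events.append(
                SafetyEvent(
                    t=m.t, kind=EventKind.HYPOCALCEMIA, value=m.pcai,
                    action="check symptoms; supplement calcium",
                )
            )
        if m.pca_total is not None and m.pcai:
            ratio, flagged = accumulation_ratio(
                m.pca_total, m.pcai, config.accumulation_ratio_threshold
            )
            if flagged:
                events.append(
                    SafetyEvent(
                        t=m.t, kind=EventKind.CITRATE_ACCUMULATION, value=ratio,
                        action="total/ionized calcium ratio above threshold",
                    )
                )
    if not tmps:
        return SessionOutcome.NOT_EVALUABLE, events
    baseline = tmps[0]
    rise = max(tmps) - baseline
    if not record.completed:
        events.append(
            SafetyEvent(
                t=record.duration, kind=EventKind.TF, value=rise,
                action="treatment could not be completed",
            )
        )
        return SessionOutcome.TF, events
    if rise > config.ptf_tmp_rise:
        events.append(
            SafetyEvent(
                t=record.duration, kind=EventKind.PTF, value=rise,
                action=f"TMP rise {rise:.0f} mmHg above PTF threshold",
            )
        )
        return SessionOutcome.PTF, events
    return SessionOutcome.COMPLETED, events


def audit_cohort(
    records: Sequence[SessionRecord], config: SafetyConfig = SafetyConfig()
) -> pd.DataFrame:
    """Audit a set of sessions: counts and percentages per safety category.

    Percentages are ``100 * count / total`` rounded to one decimal. The
    returned frame carries one row per category plus the session labels in
    each category.
    """
    if not records:
        raise ValueError("need at least one session record")
    n = len(records)
    categories: dict[str, list[str]] = {
        "hypocalcemia": [],
        "ptf": [],
        "tf": [],
        "in_window_t5": [],
        "underdosed_t5": [],
        "overdosed_t5": [],
        "citrate_accumulation": [],
    }
    for r in records:
        label = r.patient.patient_id
        outcome, events = classify_session(r, config)
        kinds = {e.kind for e in events}
        if EventKind.HYPOCALCEMIA in kinds:
            categories["hypocalcemia"].append(label)
        if EventKind.CITRATE_ACCUMULATION in kinds:
            categories["citrate_accumulation"].append(label)
        if outcome is SessionOutcome.PTF:
            categories["ptf"].append(label)
        elif outcome is SessionOutcome.TF:
            categories["tf"].append(label)
        c5 = r.ccai_t5
        if c5 is not None:
            low, high = r.prescription.target_window
            if c5 < low:
                categories["overdosed_t5"].append(label)
            elif c5 > high:
                categories["underdosed_t5"].append(label)
            else:
                categories["in_window_t5"].append(label)
    rows = [
        {
            "category": cat,
            "count": len(sessions),
            "total": n,
            "percent": round(100.0 * len(sessions) / n, 1),
            "sessions": tuple(sessions),
        }
        for cat, sessions in categories.items()
    ]
    return pd.DataFrame(rows).set_index("category")


def lint_prescription(
    q_blood: float,
    q_substitution: float,
    ffp_fraction: float,
) -> list[str]:
    """Advisory warnings for FFP-heavy replacement plans.

    FFP carries a large citrate load with no anticoagulant value; during
    FFP-based substitution blood flow should be lowered to 120-150 mL/min and
    the replacement rate should not exceed 1600 mL/h. These are advisories,
    not hard constraints.
    """
    warnings: list[str] = []
    if ffp_fraction > 0.5:
        if q_blood > 150.0:
            warnings.append(
                f"FFP-heavy replacement ({ffp_fraction:.0%}): consider lowering "
                f"blood flow from {q_blood:.0f} to 120-150 mL/min to limit the "
                "citrate load"
            )
        if q_substitution * 60.0 > 1600.0:
            warnings.append(
                f"FFP-heavy replacement: substitution rate "
                f"{q_substitution * 60:.0f} mL/h exceeds the advised 1600 mL/h"
            )
    return warnings
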