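"""Individualized citrate dosing for RCA plasma exchange.

The prescription model rests on two clinical observations:

1. Citrate is dosed per litre of *whole blood* but distributes only in
   plasma, so its effective plasma concentration is ``pCi = WBCi / (1 - Ht)``.
2. The citrate needed per millimole of chelated ionized calcium, the ratio
   ``q = pCi / dCai`` with ``dCai = pCai(t0) - cCai(t5)``, falls with the
   pre-treatment ionized calcium: hypocalcemic patients are relatively
   resistant to citrate.

A quadratic ``q(x) = a0 + a1*x + a2*x**2`` is fitted to in-window sessions by
ordinary least squares; anchoring the desired circuit ionized calcium at the
window midpoint then yields the cubic plasma dose

    pCi(x) = q(x) * (x - anchor),        x = pre-treatment pCai,

and, after hematocrit scaling, the individual whole-blood prescription.

Two surfaces are provided: plain functions (``fit_ratio_curve``,
``final_plasma_dose``, ...) and a model/results pair
(:class:`RatioCurveModel` / :class:`RatioCurveResults`) for interactive use.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import citrate_pump_rate
from .domain import (
    ACD_A,
    DEFAULT_TARGET_WINDOW,
    PatientState,
    Prescription,
    Protocol,
    Solution,
)

__all__ = [
    "PRELIMINARY_RATIO",
    "DoseResponsePoint",
    "RatioCurve",
    "DoseCurveExtrapolationWarning",
    "NegativeDoseWarning",
    "DoseClass",
    "plasma_citrate_from_whole_blood",
    "whole_blood_from_plasma",
    "preliminary_plasma_dose",
    "preliminary_whole_blood_dose",
    "fit_ratio_curve",
    "final_plasma_dose",
    "final_whole_blood_dose",
    "classify_dosing",
    "adapt_dose",
    "recalibrate_ionometer",
    "to_massic_points",
    "RatioCurveModel",
    "RatioCurveResults",
]

#: Empirical plasma citrate needed per mmol/L of pre-treatment ionized
#: calcium under the preliminary linear protocol, mmol/mmol.
PRELIMINARY_RATIO = 4.6

#: Largest whole-blood dose change allowed in one adaptation step, mmol/L.
MAX_ADAPT_STEP_WBCI = 1.2


class DoseCurveExtrapolationWarning(UserWarning):
    """Raised when a dose is requested outside the curve's fitted domain."""


class NegativeDoseWarning(UserWarning):
    """Raised when the cubic dose equation goes negative and is clamped to 0."""


@dataclass(frozen=True)
class DoseResponsePoint:
    """One session's paired dosing observation used for curve fitting."""

    pcai0: float  # pre-treatment ionized calcium, mmol/L
    pci: float  # prescribed plasma citrate, mmol/L
    ccai_t5: float  # circuit ionized calcium at 5 min, mmol/L
    qm_citrate: Optional[float] = None  # citrate massic flow, mmol/min
    qm_pcai0: Optional[float] = None  # calcium massic flow, mmol/min

    @property
    def delta_cai(self) -> float:
        """Ionized calcium chelated per litre of plasma, mmol/L."""
        return self.pcai0 - self.ccai_t5

    @property
    def ratio(self) -> float:
        """Citrate per chelated calcium, ``pci / delta_cai`` (mmol/mmol)."""
        return self.pci / self.delta_cai


@dataclass(frozen=True)
class RatioCurve:
    """A fitted citrate-requirement curve and its derived cubic dose equation.

    ``coefficients`` are ``(a0, a1, a2)`` of the quadratic
    ``q(x) = a0 + a1*x + a2*x**2`` in mmol citrate per mmol chelated calcium,
    with ``x`` the pre-treatment ionized calcium in mmol/L.
    """

    coefficients: tuple[float, float, float]
    anchor_ccai: float = 0.285
    domain: tuple[float, float] = (0.4, 1.4)
    fit_r2: float = float("nan")
    n_points: int = 0
    n_excluded: int = 0
    created_from: str = "unspecified"

    def ratio(self, pcai0) -> np.ndarray | float:
        """Evaluate ``q(pcai0)``."""
        a0, a1, a2 = self.coefficients
        return a0 + a1 * np.asarray(pcai0, dtype=float) + a2 * np.asarray(pcai0, dtype=float) ** 2

    def plasma_dose(self, pcai0: float) -> float:
        """Cubic plasma dose ``q(pcai0) * (pcai0 - anchor)``, clamped at 0."""
        return final_plasma_dose(pcai0, self)

    def to_dict(self) -> dict:
        return {
            "coefficients": list(self.coefficients),
            "anchor_ccai": self.anchor_ccai,
            "domain": list(self.domain),
            "fit_r2": self.fit_r2,
            "n_points": self.n_points,
            "n_excluded": self.n_excluded,
            "created_from": self.created_from,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RatioCurve":
        return cls(
            coefficients=tuple(float(c) for c in d["coefficients"]),
            anchor_ccai=float(d.get("anchor_ccai", 0.285)),
            domain=tuple(float(v) for v in d.get("domain", (0.4, 1.4))),
            fit_r2=float(d.get("fit_r2", float("nan"))),
            n_points=int(d.get("n_points", 0)),
            n_excluded=int(d.get("n_excluded", 0)),
            created_from=str(d.get("created_from", "unspecified")),
        )

    @classmethod
    def from_json(cls, path) -> "RatioCurve":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# whole blood <-> plasma conversion


def plasma_citrate_from_whole_blood(wbci: float, hematocrit: float) -> float:
    """Plasma citrate concentration from a whole-blood dose: ``wbci/(1-Ht)``.

    Citrate does not enter the erythrocyte, so a dose expressed per litre of
    whole blood concentrates into the plasma fraction.
    """
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError(f"hematocrit: {hematocrit!r} must lie in [0, 1)")
    return wbci / (1.0 - hematocrit)


def whole_blood_from_plasma(pci: float, hematocrit: float) -> float:
    """Inverse of :func:`plasma_citrate_from_whole_blood`: ``pci * (1 - Ht)``."""
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError(f"hematocrit: {hematocrit!r} must lie in [0, 1)")
    return pci * (1.0 - hematocrit)


# ---------------------------------------------------------------------------
# preliminary (linear) protocol


def preliminary_plasma_dose(pcai0: float, ratio: float = PRELIMINARY_RATIO) -> float:
    """Preliminary plasma citrate dose: a constant ratio times pCai(t0)."""
    if pcai0 < 0:
        raise ValueError("pcai0: must be non-negative")
    return ratio * pcai0


def preliminary_whole_blood_dose(
    pcai0: float, hematocrit: float, ratio: float = PRELIMINARY_RATIO
) -> float:
    """Preliminary whole-blood dose: the plasma dose scaled by ``(1 - Ht)``."""
    return whole_blood_from_plasma(preliminary_plasma_dose(pcai0, ratio), hematocrit)


# ---------------------------------------------------------------------------
# quadratic ratio-curve fitting


def _fit_quadratic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS quadratic fit; returns (coefficients low->high, R^2)."""
    design = np.vander(x, 3, increasing=True)
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError(
            "singular design: pre-treatment pCai values do not span a quadratic "
            "(need at least 3 distinct values)"
        )
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coefs
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return coefs, float(np.clip(r2, 0.0, 1.0))


def fit_ratio_curve(
    points: Sequence[DoseResponsePoint],
    window: tuple[float, float] = DEFAULT_TARGET_WINDOW,
    anchor: Optional[float] = None,
    created_from: str = "fit",
) -> RatioCurve:
    """Fit the quadratic citrate-requirement curve ``q(pCai0)`` by OLS.

    Only sessions whose circuit ionized calcium at 5 minutes lies inside the
    target ``window`` are retained, mirroring the study's in-window fitting;
    the number excluded is reported on the returned curve. The anchor defaults
    to the window midpoint.

    Raises
    ------
    ValueError
        If fewer than 4 usable points remain, any retained point has a
        non-positive calcium drop, or all retained pCai0 coincide.
    """
    low, high = window
    retained = [p for p in points if low <= p.ccai_t5 <= high]
    n_excluded = len(points) - len(retained)
    if len(retained) < 4:
        raise ValueError(
            f"need at least 4 in-window points to fit the ratio curve "
            f"(got {len(retained)} of {len(points)}; {n_excluded} outside "
            f"[{low}, {high}])"
        )
    bad = [p for p in retained if p.delta_cai <= 0]
    if bad:
        raise ValueError(
            f"{len(bad)} point(s) have non-positive delta_cai; the ratio is "
            "undefined without a calcium drop"
        )
    x = np.array([p.pcai0 for p in retained], dtype=float)
    y = np.array([p.ratio for p in retained], dtype=float)
    coefs, r2 = _fit_quadratic(x, y)
    if anchor is None:
        anchor = 0.5 * (low + high)
    return RatioCurve(
        coefficients=(float(coefs[0]), float(coefs[1]), float(coefs[2])),
        anchor_ccai=float(anchor),
        domain=(float(x.min()), float(x.max())),
        fit_r2=r2,
        n_points=len(retained),
        n_excluded=n_excluded,
        created_from=created_from,
    )


def to_massic_points(
    points: Iterable[DoseResponsePoint], q_plasma_inflow: float
) -> list[DoseResponsePoint]:
    """Re-express concentration points as massic flows (mmol/min).

    Multiplying both axes by the filter plasma inflow turns the
    concentration-based ratio relation into its massic-flow analogue. This is
    a reporting view — the underlying regression model is unchanged.
    """
    if q_plasma_inflow <= 0:
        raise ValueError("q_plasma_inflow: must be positive")
    f = q_plasma_inflow / 1000.0
    return [
        replace(p, qm_citrate=p.pci * f, qm_pcai0=p.pcai0 * f) for p in points
    ]


# ---------------------------------------------------------------------------
# final (cubic) protocol


def final_plasma_dose(pcai0: float, curve: RatioCurve) -> float:
    """Cubic plasma dose from the fitted curve: ``q(pcai0)*(pcai0 - anchor)``.

    Outside the curve's fitted domain the dose is still computed but a
    :class:`DoseCurveExtrapolationWarning` is emitted — the curve was built
    from in-domain sessions only, and bias is expected in the upper pCai
    range where calibration data are sparse. Negative values (pCai below the
    anchor) are clamped to zero with a :class:`NegativeDoseWarning`.
    """
    lo, hi = curve.domain
    if not lo <= pcai0 <= hi:
        warnings.warn(
            f"pcai0={pcai0:.3f} outside fitted domain [{lo:.3f}, {hi:.3f}]; "
            "dose is an extrapolation",
            DoseCurveExtrapolationWarning,
            stacklevel=2,
        )
    dose = float(curve.ratio(pcai0)) * (pcai0 - curve.anchor_ccai)
    if dose < 0:
        warnings.warn(
            f"cubic dose negative ({dose:.3f} mmol/L) at pcai0={pcai0:.3f}; "
            "clamped to 0",
            NegativeDoseWarning,
            stacklevel=2,
        )
        return 0.0
    return dose


def final_whole_blood_dose(
    patient: PatientState,
    curve: RatioCurve,
    q_blood: float = 200.0,
    anticoagulant: Solution = ACD_A,
    window: tuple[float, float] = DEFAULT_TARGET_WINDOW,
) -> Prescription:
    """Individual whole-blood prescription from the fitted curve.

    The plasma dose is scaled by ``(1 - Ht)`` and converted to a citrate pump
    rate for the given blood flow and anticoagulant.
    """
    pci = final_plasma_dose(patient.pcai0, curve)
    wbci = whole_blood_from_plasma(pci, patient.hematocrit)
    return Prescription(
        wbci=wbci,
        pci=pci,
        citrate_pump=citrate_pump_rate(wbci, q_blood, anticoagulant),
        target_window=window,
        protocol=Protocol.FINAL,
    )


class DoseClass(str, enum.Enum):
    OVERDOSED = "overdosed"
    IN_RANGE = "in_range"
    UNDERDOSED = "underdosed"


def classify_dosing(
    ccai_t5: float, window: tuple[float, float] = DEFAULT_TARGET_WINDOW
) -> DoseClass:
    """Classify a 5-minute circuit ionized calcium against the target window.

    Circuit calcium *below* the window means too much citrate (overdosed);
    *above* means too little (underdosed). Window endpoints are in range.
    """
    if ccai_t5 < 0:
        raise ValueError("ccai_t5: must be non-negative")
    low, high = window
    if ccai_t5 < low:
        return DoseClass.OVERDOSED
    if ccai_t5 > high:
        return DoseClass.UNDERDOSED
    return DoseClass.IN_RANGE


def adapt_dose(
    prescription: Prescription,
    observed_ccai: float,
    patient: PatientState,
    curve: RatioCurve,
    q_blood: float = 200.0,
    anticoagulant: Solution = ACD_A,
) -> Prescription:
    """One conservative dose-adaptation step from an observed circuit calcium.

    If the observation is in range the prescription is returned unchanged.
    Otherwise the curve's local requirement ``q(pCai0)`` converts the miss
    ``observed - anchor`` into the extra (or surplus) plasma citrate needed to
    bring the circuit calcium to the anchor — one Newton-style step — and the
    whole-blood change is capped at ±1.2 mmol/L per adjustment. The result is
    flagged ``adapted`` and should be re-checked at the next scheduled
    measurement.
    """
    if observed_ccai <= 0:
        raise ValueError("observed_ccai: must be positive")
    if classify_dosing(observed_ccai, prescription.target_window) is DoseClass.IN_RANGE:
        return prescription
    anchor = curve.anchor_ccai
    delta_pci = float(curve.ratio(patient.pcai0)) * (observed_ccai - anchor)
    delta_wbci = whole_blood_from_plasma(delta_pci, patient.hematocrit)
    delta_wbci = float(np.clip(delta_wbci, -MAX_ADAPT_STEP_WBCI, MAX_ADAPT_STEP_WBCI))
    new_wbci = max(0.0, prescription.wbci + delta_wbci)
    new_pci = plasma_citrate_from_whole_blood(new_wbci, patient.hematocrit)
    return Prescription(
        wbci=new_wbci,
        pci=new_pci,
        citrate_pump=citrate_pump_rate(new_wbci, q_blood, anticoagulant),
        target_window=prescription.target_window,
        protocol=prescription.protocol,
        adapted=True,
    )


def recalibrate_ionometer(
    paired_readings: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Affine correction mapping a local ionometer onto the reference device.

    Ionometers are often not validated in the low circuit-calcium range used
    for RCA; a site must calibrate the protocol against its own device. Given
    paired ``(reference, local)`` readings this returns ``(slope, intercept)``
    of the least-squares map ``reference ~ slope * local + intercept``.
    """
    if len(paired_readings) < 2:
        raise ValueError("need at least 2 paired readings")
    ref = np.array([r for r, _ in paired_readings], dtype=float)
    loc = np.array([l for _, l in paired_readings], dtype=float)
    if np.ptp(loc) == 0:
        raise ValueError("degenerate input: all local readings identical")
    slope, intercept = np.polyfit(loc, ref, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# model / results surface


class RatioCurveModel:
    """Citrate-requirement curve model over paired dosing observations.

    Parameters
    ----------
    data : sequence of DoseResponsePoint or pandas.DataFrame
        A DataFrame must carry columns ``pcai0``, ``pci`` and ``ccai_t5``.
    window : (low, high)
        Target circuit ionized-calcium window; only in-window sessions are
        used in the fit and the anchor defaults to the midpoint.

    Examples
    --------
    >>> model = RatioCurveModel.from_dataframe(df)
    >>> res = model.fit()
    >>> res.rsquared
    0.72...
    >>> res.prescribe(patient).wbci
    3.2...
    """

    def __init__(
        self,
        data: Sequence[DoseResponsePoint],
        window: tuple[float, float] = DEFAULT_TARGET_WINDOW,
        anchor: Optional[float] = None,
    ):
        self.points = list(data)
        self.window = (float(window[0]), float(window[1]))
        self.anchor = anchor

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        window: tuple[float, float] = DEFAULT_TARGET_WINDOW,
        anchor: Optional[float] = None,
    ) -> "RatioCurveModel":
        pts = [
            DoseResponsePoint(
                pcai0=float(r.pcai0), pci=float(r.pci), ccai_t5=float(r.ccai_t5)
            )
            for r in df.itertuples(index=False)
        ]
        return cls(pts, window=window, anchor=anchor)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RatioCurveModel":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def fit(self) -> "RatioCurveResults":
        curve = fit_ratio_curve(
            self.points, window=self.window, anchor=self.anchor, created_from="fit"
        )
        low, high = self.window
        excluded = [p for p in self.points if not low <= p.ccai_t5 <= high]
        return RatioCurveResults(model=self, curve=curve, excluded=excluded)


@dataclass
class RatioCurveResults:
    """Fit results: the curve, diagnostics and prescription helpers."""

    model: RatioCurveModel
    curve: RatioCurve
    excluded: list[DoseResponsePoint] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        """Quadratic coefficients ``(a0, a1, a2)``, low order first."""
        return np.asarray(self.curve.coefficients)

    @property
    def rsquared(self) -> float:
        return self.curve.fit_r2

    @property
    def nobs(self) -> int:
        return self.curve.n_points

    def predict(self, pcai0) -> np.ndarray | float:
        """Citrate-requirement ratio ``q(pcai0)``, mmol per mmol."""
        return self.curve.ratio(pcai0)

    def plasma_dose(self, pcai0: float) -> float:
        """Cubic plasma dose at a pre-treatment pCai, mmol/L."""
        return final_plasma_dose(pcai0, self.curve)

    def prescribe(
        self,
        patient: PatientState,
        q_blood: float = 200.0,
        anticoagulant: Solution = ACD_A,
    ) -> Prescription:
        return final_whole_blood_dose(
            patient, self.curve, q_blood=q_blood, anticoagulant=anticoagulant,
            window=self.model.window,
        )

    def summary(self) -> str:
        a0, a1, a2 = self.curve.coefficients
        lo, hi = self.curve.domain
        lines = [
            "Citrate requirement curve (OLS quadratic)",
            "=" * 45,
            f"q(x) = {a0:+.4f} {a1:+.4f}*x {a2:+.4f}*x^2   [mmol/mmol]",
            f"cubic dose: pCi(x) = q(x)*(x - {self.curve.anchor_ccai:.3f})",
            f"R^2                 {self.curve.fit_r2:.3f}",
            f"n (in window)       {self.curve.n_points}",
            f"n excluded          {self.curve.n_excluded}",
            f"fitted domain       [{lo:.3f}, {hi:.3f}] mmol/L",
            f"target window       [{self.model.window[0]:.2f}, "
            f"{self.model.window[1]:.2f}] mmol/L",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.curve.to_json(path)

    def plot_fit(self, ax=None):
        """Scatter of observed ratios with the fitted quadratic overlaid."""
        from .plotting import plot_ratio_fit

        return plot_ratio_fit(self.curve, self.model.points, ax=ax)

    def plot_dose_curve(self, ax=None):
        """The derived cubic plasma-dose curve over the fitted domain."""
        from .plotting import plot_dose_curve

        return plot_dose_curve(self.curve, ax=ax)
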