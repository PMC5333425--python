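"""Diagnostic plots for the dosing pipeline (matplotlib, Agg-safe)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .domain import SessionRecord
from .dosing import DoseResponsePoint, RatioCurve

__all__ = ["plot_ratio_fit", "plot_dose_curve", "plot_session"]


def _axes(ax=None):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_ratio_fit(
    curve: RatioCurve, points: Optional[Sequence[DoseResponsePoint]] = None, ax=None
):
    """Observed citrate-per-chelated-calcium ratios with the fitted quadratic."""
    ax = _axes(ax)
    xs = np.linspace(*curve.domain, 200)
    ax.plot(xs, curve.ratio(xs), "-", color="C0", label="fitted quadratic q(x)")
    if points:
        px = [p.pcai0 for p in points]
        py = [p.ratio for p in points if p.delta_cai > 0]
        ax.plot(px[: len(py)], py, "o", ms=4, color="C1", alpha=0.7, label="sessions")
    ax.set_xlabel("pre-treatment pCai [mmol/L]")
    ax.set_ylabel("pCi / ΔCai [mmol/mmol]")
    ax.legend(frameon=False)
    ax.set_title(f"citrate requirement ratio (R² = {curve.fit_r2:.3f})")
    return ax


def plot_dose_curve(curve: RatioCurve, ax=None):
    """Cubic plasma-dose curve over the fitted domain."""
    ax = _axes(ax)
    xs = np.linspace(*curve.domain, 200)
    doses = np.maximum(curve.ratio(xs) * (xs - curve.anchor_ccai), 0.0)
    ax.plot(xs, doses, "-", color="C0")
    ax.axvline(curve.anchor_ccai, ls=":", color="gray", lw=0.8)
    ax.set_xlabel("pre-treatment pCai [mmol/L]")
    ax.set_ylabel("plasma citrate dose pCi [mmol/L]")
    ax.set_title("individualized plasma citrate dose")
    return ax


def plot_session(record: SessionRecord, ax=None):
    """Systemic/circuit calcium and TMP course of one simulated session."""
    ax = _axes(ax)
    t = [m.t for m in record.measurements]
    for attr, style, label in (
        ("pcai", "o-", "systemic pCai"),
        ("ccai", "s-", "circuit cCai"),
        ("pca_total", "^-", "total pCa"),
    ):
        ys = [getattr(m, attr) for m in record.measurements]
        if all(y is not None for y in ys):
            ax.plot(t, ys, style, ms=4, label=label)
    ax.set_xlabel("time [min]")
    ax.set_ylabel("calcium [mmol/L]")
    ax2 = ax.twinx()
    tmp = [m.tmp for m in record.measurements]
    if all(v is not None for v in tmp):
        ax2.plot(t, tmp, "--", color="gray", label="TMP")
        ax2.set_ylabel("TMP [mmHg]")
    ax.legend(frameon=False, loc="center right")
    return ax
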