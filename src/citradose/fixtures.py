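"""Packaged reference tables from the source study cohort.

Two small CSV tables ship with the package:

* ``table2.csv`` — the first five TPE sessions of the discovery phase, dosed
  at a fixed whole-blood citrate concentration while aiming a deliberately
  high circuit ionized calcium of 0.35-0.40 mmol/L. All five showed partial
  treatment failure (TMP elevation), which motivated lowering the target
  window.
* ``table3.csv`` — paired pre/post-treatment plasma values (mean ± SD) of
  ionized calcium, total calcium, their ratio, pH and bicarbonate over the
  documented sessions.

Both are transcribed as printed, including formatting quirks (see
:func:`load_fixture_table2`).
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import NamedTuple, Optional

__all__ = [
    "Table2Row",
    "Table3Row",
    "load_fixture_table2",
    "load_fixture_table3",
    "table2_path",
    "table3_path",
]


class Table2Row(NamedTuple):
    """One discovery-phase session (fixed whole-blood citrate dosing)."""

    session: str
    hematocrit: float  # fraction (the table prints percent)
    pcai0: float  # mmol/L
    wbci: float  # mmol/L whole blood
    ccai_t5: float  # mmol/L
    ccai_max: float  # mmol/L
    ptf_flag: bool
    tf_flag: bool
    ptf_raw: str
    tf_raw: str


class Table3Row(NamedTuple):
    """Paired pre/post-treatment cohort means (``None`` where not printed)."""

    quantity: str
    pre_mean: Optional[float]
    pre_sd: Optional[float]
    post_mean: Optional[float]
    post_sd: Optional[float]


def _data_file(name: str):
    return resources.files("citradose.data").joinpath(name)


def table2_path() -> str:
    """Filesystem path of the packaged five-session table."""
    return str(_data_file("table2.csv"))


def table3_path() -> str:
    """Filesystem path of the packaged pre/post plasma-values table."""
    return str(_data_file("table3.csv"))


def load_fixture_table2() -> list[Table2Row]:
    """Load the five fixed-dose discovery sessions.

    Hematocrit is returned as a fraction (the source prints percent). The PTF
    and TF columns are returned both as booleans and as the raw printed cells:
    row C.1 prints its PTF flag as a lowercase ``"y"`` (and leaves TF blank)
    even though the surrounding text states that the first five sessions all
    showed TMP elevation; the table is stored exactly as printed and the
    lowercase cell is treated as an affirmative flag.
    """
    rows: list[Table2Row] = []
    with _data_file("table2.csv").open("r", encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                Table2Row(
                    session=rec["session"],
                    hematocrit=float(rec["ht_percent"]) / 100.0,
                    pcai0=float(rec["pcai0"]),
                    wbci=float(rec["wbci"]),
                    ccai_t5=float(rec["ccai_t5"]),
                    ccai_max=float(rec["ccai_max"]),
                    ptf_flag=rec["ptf"].strip().lower() == "y",
                    tf_flag=rec["tf"].strip().lower() == "y",
                    ptf_raw=rec["ptf"],
                    tf_raw=rec["tf"],
                )
            )
    if len(rows) != 5:
        raise RuntimeError("packaged table2.csv must contain exactly 5 sessions")
    return rows


def load_fixture_table3() -> list[Table3Row]:
    """Load the paired pre/post-treatment plasma values (mean ± SD).

    The pre-treatment cell of the total-to-ionized calcium ratio is not
    printed in the source table and is returned as ``None``.
    """

    def _opt(cell: str) -> Optional[float]:
        cell = cell.strip()
        return float(cell) if cell else None

    rows: list[Table3Row] = []
    with _data_file("table3.csv").open("r", encoding="utf-8", newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                Table3Row(
                    quantity=rec["quantity"],
                    pre_mean=_opt(rec["pre_mean"]),
                    pre_sd=_opt(rec["pre_sd"]),
                    post_mean=_opt(rec["post_mean"]),
                    post_sd=_opt(rec["post_sd"]),
                )
            )
    return rows
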