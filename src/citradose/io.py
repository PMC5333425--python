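"""File schemas: curve JSON, session records, dose-response CSV, run metadata.

Machine-readable outputs embed the tool version, a hash of the producing
configuration and the random seed, so every artifact can be traced to the
run that wrote it.
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .domain import Measurement, SessionRecord
from .dosing import DoseResponsePoint

__all__ = [
    "artifact_meta",
    "config_hash",
    "points_to_csv",
    "points_from_csv",
    "session_to_json",
    "session_from_json",
    "measurements_to_csv",
]

POINT_COLUMNS = ["pcai0", "pci", "ccai_t5"]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def artifact_meta(seed: Optional[int] = None, config: Optional[dict] = None) -> dict:
    """Provenance block embedded in every output artifact."""
    return {
        "tool": "citradose",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }


def points_to_csv(points: Sequence[DoseResponsePoint], path) -> None:
    """Write dose-response points as a tidy CSV (one session per row)."""
    pd.DataFrame(
        [{"pcai0": p.pcai0, "pci": p.pci, "ccai_t5": p.ccai_t5} for p in points]
    ).to_csv(path, index=False)


def points_from_csv(path) -> list[DoseResponsePoint]:
    """Read dose-response points, reporting row-level problems."""
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response CSV is missing columns: {missing}")
    bad = df.index[df[POINT_COLUMNS].isna().any(axis=1) | (df[POINT_COLUMNS] < 0).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"dose-response CSV has missing/negative values in rows: {list(bad)}"
        )
    return [
        DoseResponsePoint(pcai0=float(r.pcai0), pci=float(r.pci), ccai_t5=float(r.ccai_t5))
        for r in df.itertuples(index=False)
    ]


def session_to_json(record: SessionRecord, path, seed: Optional[int] = None) -> None:
    """Persist one session record (metadata + measurements + events) as JSON."""
    payload = {"meta": artifact_meta(seed=seed), "session": record.model_dump(mode="json")}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def session_from_json(path) -> SessionRecord:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return SessionRecord.model_validate(payload["session"])


def measurements_to_csv(measurements: Sequence[Measurement], path) -> None:
    """Tidy per-measurement CSV (one row per time point)."""
    pd.DataFrame([m.model_dump() for m in measurements]).to_csv(path, index=False)
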