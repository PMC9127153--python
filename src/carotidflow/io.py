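"""CSV plumbing: waveform, truth and results tables.

All files are UTF-8 CSV with headers; floats are written with ``repr``
precision so numeric round trips are loss-free to 1e-12 or better.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamics import (
    BloodProperties,
    VelocityWaveform,
    VesselGeometry,
    classify_flow,
    ess_waveform,
    reynolds_from_waveform,
)
from .synthetic import SyntheticRecord

WAVEFORM_COLUMNS = [
    "participant_id",
    "sex",
    "modality",
    "intensity",
    "time_s",
    "velocity_m_s",
    "diameter_m",
    "hematocrit",
    "period_s",
]
TRUTH_COLUMNS = ["participant_id", "sex", "modality", "intensity", "true_ess_dyn_cm2"]
RESULTS_COLUMNS = [
    "participant_id",
    "sex",
    "modality",
    "intensity",
    "ess_mean_dyn_cm2",
    "ess_peak_dyn_cm2",
    "reynolds",
    "regime",
]

_KEY = ["participant_id", "sex", "modality", "intensity"]


@dataclass(frozen=True)
class WaveformRecord:
    """One condition record reassembled from the long waveform CSV."""

    participant_id: str
    sex: str
    modality: str
    intensity: str
    waveform: VelocityWaveform
    geometry: VesselGeometry
    blood: BloodProperties


def waveforms_to_frame(records: list[SyntheticRecord]) -> pd.DataFrame:
    chunks = []
    for rec in records:
        w = rec.waveform
        chunks.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "sex": rec.sex,
                    "modality": rec.modality,
                    "intensity": rec.intensity,
                    "time_s": w.t,
                    "velocity_m_s": w.v,
                    "diameter_m": rec.diameter,
                    "hematocrit": rec.hematocrit,
                    "period_s": w.period,
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)[WAVEFORM_COLUMNS]


def export_waveforms(records: list[SyntheticRecord], path: str | Path) -> Path:
    path = Path(path)
    waveforms_to_frame(records).to_csv(path, index=False, float_format="%.17g")
    return path


def truth_frame(records: list[SyntheticRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "sex": [r.sex for r in records],
            "modality": [r.modality for r in records],
            "intensity": [r.intensity for r in records],
            "true_ess_dyn_cm2": [r.true_ess for r in records],
        }
    )


def export_truth(records: list[SyntheticRecord], path: str | Path) -> Path:
    path = Path(path)
    truth_frame(records).to_csv(path, index=False, float_format="%.17g")
    return path


def read_truth(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, TRUTH_COLUMNS, path)
    return frame


def read_waveforms(path: str | Path) -> list[WaveformRecord]:
    frame = pd.read_csv(path)
    _require_columns(frame, WAVEFORM_COLUMNS, path)
    records = []
    for key, group in frame.groupby(_KEY, sort=False):
        first = group.iloc[0]
        try:
            waveform = VelocityWaveform(
                t=group["time_s"].to_numpy(),
                v=group["velocity_m_s"].to_numpy(),
                period=float(first["period_s"]),
            )
        except ValueError as exc:
            line = int(group.index[0]) + 2  # header is line 1
            raise ValueError(
                f"invalid waveform for record {key} starting at line {line}: {exc}"
            ) from exc
        hct = first["hematocrit"]
        records.append(
            WaveformRecord(
                participant_id=str(first["participant_id"]),
                sex=str(first["sex"]),
                modality=str(first["modality"]),
                intensity=str(first["intensity"]),
                waveform=waveform,
                geometry=VesselGeometry(float(first["diameter_m"])),
                blood=BloodProperties(
                    hematocrit=None if pd.isna(hct) else float(hct)
                ),
            )
        )
    return records


def compute_results(
    records: list[WaveformRecord], n_harmonics: int = 8
) -> pd.DataFrame:
    """Run the shear/Reynolds pipeline over condition records."""
    rows = []
    for rec in records:
        shear = ess_waveform(rec.waveform, rec.geometry, rec.blood, n_harmonics)
        re = reynolds_from_waveform(rec.waveform, rec.geometry, rec.blood)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "sex": rec.sex,
                "modality": rec.modality,
                "intensity": rec.intensity,
                "ess_mean_dyn_cm2": shear.mean_ess,
                "ess_peak_dyn_cm2": shear.peak_ess,
                "reynolds": re,
                "regime": classify_flow(re).regime,
            }
        )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def write_results(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame[RESULTS_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(frame, RESULTS_COLUMNS, path)
    return frame


def results_from_records(
    records: list[SyntheticRecord], n_harmonics: int = 8
) -> pd.DataFrame:
    """Convenience: pipeline results straight from in-memory synthetic records."""
    wrecs = [
        WaveformRecord(
            participant_id=r.participant_id,
            sex=r.sex,
            modality=r.modality,
            intensity=r.intensity,
            waveform=r.waveform,
            geometry=VesselGeometry(r.diameter),
            blood=BloodProperties(hematocrit=r.hematocrit),
        )
        for r in records
    ]
    return compute_results(wrecs, n_harmonics)


def _require_columns(frame: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
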