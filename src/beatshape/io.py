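"""Plain-text readers and writers for every pipeline artifact.

All tables are comma-separated UTF-8 CSV with a header row and '.' decimal;
signals are two-column (time_ms, voltage_mV) CSV; models are JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Cohort, EcgRecord, GlucoseSeries

__all__ = [
    "write_ecg_csv",
    "read_ecg_csv",
    "write_glucose_csv",
    "read_glucose_csv",
    "write_cohort",
    "write_beat_table",
    "read_beat_table",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def write_ecg_csv(record: EcgRecord, path) -> None:
    t_ms = np.arange(len(record.signal_mv)) * 1000.0 / record.fs_hz
    pd.DataFrame({"time_ms": t_ms, "voltage_mV": record.signal_mv}).to_csv(path, index=False)


def read_ecg_csv(path, rat_id: str = "", diabetic: bool = False, died: bool = False) -> EcgRecord:
    df = pd.read_csv(path)
    _require_columns(df, ["time_ms", "voltage_mV"], path)
    t = df["time_ms"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform sampling")
        fs = 1000.0 / dt[0]
    else:
        fs = 1000.0
    return EcgRecord(
        rat_id=rat_id or Path(path).stem,
        fs_hz=float(fs),
        signal_mv=df["voltage_mV"].to_numpy(dtype=float),
        diabetic=diabetic,
        died=died,
    )


def write_glucose_csv(series: GlucoseSeries, path) -> None:
    pd.DataFrame(
        {"time_min": series.times_min, "glucose_mg_dl": series.values_mgdl}
    ).to_csv(path, index=False)


def read_glucose_csv(path) -> GlucoseSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["time_min", "glucose_mg_dl"], path)
    return GlucoseSeries(
        times_min=df["time_min"].to_numpy(dtype=float),
        values_mgdl=df["glucose_mg_dl"].to_numpy(dtype=float),
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """ECG, glucose, ground truth per rat plus a cohort metadata table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    for rat in cohort.rats:
        write_ecg_csv(cohort.records[rat.rat_id], out / f"{rat.rat_id}_ecg.csv")
        write_glucose_csv(cohort.glucose[rat.rat_id], out / f"{rat.rat_id}_glucose.csv")
        cohort.truth[rat.rat_id].to_csv(out / f"{rat.rat_id}_truth.csv", index=False)


def write_beat_table(table: pd.DataFrame, trajectories: np.ndarray, path) -> None:
    """One row per beat: metadata/interval columns followed by trajectory
    sample columns t000..tNNN."""
    traj = pd.DataFrame(
        trajectories, columns=[f"t{i:03d}" for i in range(trajectories.shape[1])]
    )
    pd.concat([table.reset_index(drop=True), traj], axis=1).to_csv(path, index=False)


def read_beat_table(path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path)
    traj_cols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    if not traj_cols:
        raise ValueError(f"{path}: missing trajectory columns t000..")
    traj_cols = sorted(traj_cols, key=lambda c: int(c[1:]))
    meta_cols = [c for c in df.columns if c not in traj_cols]
    return df[meta_cols].copy(), df[traj_cols].to_numpy(dtype=float)
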