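"""Segmentation into glucose-aligned 15-minute windows and ECG filtering.

Baseline wander is removed with a zero-phase band-pass Butterworth filter
(default 0.5-100 Hz, order 3) and powerline interference with a zero-phase
notch (default 60 Hz, Q = 30). Zero-phase (forward-backward) application
keeps fiducial timing unshifted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import EcgRecord, GlucoseSeries

__all__ = [
    "Segment",
    "FilterParams",
    "segment_record",
    "remove_baseline_wander",
    "remove_powerline",
    "filter_signal",
    "filter_segments",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    low_cut_hz: float = 0.5
    high_cut_hz: float = 100.0
    order: int = 3
    notch_hz: float = 60.0
    quality_factor: float = 30.0


@dataclass
class Segment:
    """One 15-minute half-open window [start_min, end_min) of a recording,
    carrying the glucose draw taken at its start."""

    rat_id: str
    segment_idx: int
    start_min: float
    end_min: float
    glucose_mg_dl: float
    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        if self.glucose_mg_dl <= 0:
            raise ValueError("glucose must be > 0")


def segment_record(record: EcgRecord, glucose: GlucoseSeries) -> list[Segment]:
    """Cut the recording into 15-minute intervals aligned with glucose draws.

    One segment per draw whose full interval is covered by signal; partial
    trailing intervals are dropped.
    """
    fs = record.fs_hz
    duration_min = len(record.signal_mv) / fs / 60.0
    times = np.asarray(glucose.times_min, dtype=float)
    if len(times) >= 2:
        cadence = float(times[1] - times[0])
    else:
        cadence = 15.0
    segments: list[Segment] = []
    idx = 0
    for t, g in zip(times, np.asarray(glucose.values_mgdl, dtype=float)):
        end = t + cadence
        if end > duration_min + 1e-9:
            continue
        i0 = int(round(t * 60.0 * fs))
        i1 = int(round(end * 60.0 * fs))
        segments.append(
            Segment(
                rat_id=record.rat_id,
                segment_idx=idx,
                start_min=float(t),
                end_min=float(end),
                glucose_mg_dl=float(g),
                samples=record.signal_mv[i0:i1],
                fs_hz=fs,
            )
        )
        idx += 1
    if not segments:
        log.warning("record %s: no glucose-aligned coverage, 0 segments", record.rat_id)
    return segments


def remove_baseline_wander(
    x: np.ndarray,
    fs_hz: float,
    low_cut_hz: float = 0.5,
    high_cut_hz: float = 100.0,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase band-pass Butterworth; removes DC and slow wander while
    keeping the ECG band."""
    nyq = fs_hz / 2.0
    if not 0.0 < low_cut_hz < high_cut_hz < nyq:
        raise ValueError("need 0 < low_cut < high_cut < fs/2")
    sos = sps.butter(order, [low_cut_hz, high_cut_hz], btype="bandpass", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def remove_powerline(
    x: np.ndarray, fs_hz: float, notch_hz: float = 60.0, quality_factor: float = 30.0
) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency."""
    if not 0.0 < notch_hz < fs_hz / 2.0:
        raise ValueError("need 0 < notch_hz < fs/2")
    b, a = sps.iirnotch(notch_hz, quality_factor, fs=fs_hz)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def filter_signal(x: np.ndarray, fs_hz: float, params: FilterParams | None = None) -> np.ndarray:
    p = params or FilterParams()
    y = remove_baseline_wander(x, fs_hz, p.low_cut_hz, p.high_cut_hz, p.order)
    return remove_powerline(y, fs_hz, p.notch_hz, p.quality_factor)


def filter_segments(segments: list[Segment], params: FilterParams | None = None) -> list[Segment]:
    """Return new segments with filtered samples."""
    out = []
    for s in segments:
        out.append(
            Segment(
                rat_id=s.rat_id,
                segment_idx=s.segment_idx,
                start_min=s.start_min,
                end_min=s.end_min,
                glucose_mg_dl=s.glucose_mg_dl,
                samples=filter_signal(s.samples, s.fs_hz, params),
                fs_hz=s.fs_hz,
            )
        )
    return out
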