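"""Scoring of delineation and clustering against synthetic ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_r_peaks", "delineation_scores"]


def match_r_peaks(
    detected: np.ndarray, truth: np.ndarray, tol_samples: int = 2
) -> tuple[float, float, np.ndarray]:
    """Greedy one-to-one matching of detected R indices to true R indices
    within ``tol_samples``.

    Returns (recall, precision, pairs) where pairs is an (m, 2) array of
    (true index position, detected index position).
    """
    detected = np.sort(np.asarray(detected, dtype=int))
    truth = np.sort(np.asarray(truth, dtype=int))
    if len(truth) == 0:
        return (np.nan, np.nan, np.empty((0, 2), dtype=int))
    pairs = []
    used = np.zeros(len(detected), dtype=bool)
    for i, t in enumerate(truth):
        lo = np.searchsorted(detected, t - tol_samples, side="left")
        hi = np.searchsorted(detected, t + tol_samples, side="right")
        for j in range(lo, hi):
            if not used[j]:
                used[j] = True
                pairs.append((i, j))
                break
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    recall = len(pairs) / len(truth)
    precision = len(pairs) / len(detected) if len(detected) else np.nan
    return recall, precision, pairs


def delineation_scores(
    beat_table: pd.DataFrame,
    truth: pd.DataFrame,
    segment_offsets: dict[int, int] | None = None,
    tol_samples: int = 2,
) -> dict:
    """Compare a delineated beat table with the generator's ground truth for
    one rat.

    ``segment_offsets`` maps segment_idx to the segment's absolute start
    sample so per-segment R indices can be compared with the record-level
    truth. Returns recall/precision and median absolute interval errors (ms)
    over matched, mutually observed beats.
    """
    if segment_offsets is None:
        segment_offsets = {}
    det = beat_table.copy()
    offs = det["segment_idx"].map(lambda s: segment_offsets.get(s, 0))
    det["abs_r"] = det["r_index"] + offs
    det = det.sort_values("abs_r").reset_index(drop=True)
    tr = truth.sort_values("r_index").reset_index(drop=True)
    recall, precision, pairs = match_r_peaks(
        det["abs_r"].to_numpy(), tr["r_index"].to_numpy(), tol_samples
    )
    out = {"recall": recall, "precision": precision, "n_matched": len(pairs)}
    for iv in ("pr_ms", "qt_ms", "qrs_ms"):
        errs = []
        for ti, di in pairs:
            t_v, d_v = tr[iv].iloc[ti], det[iv].iloc[di]
            if not (np.isnan(t_v) or np.isnan(d_v)):
                errs.append(abs(d_v - t_v))
        out[f"median_abs_err_{iv}"] = float(np.median(errs)) if errs else np.nan
    return out
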