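"""Filter and delineate one synthetic recording, then score the delineation
against the generator's ground truth.

Shows the full preprocessing path: glucose-aligned 15-minute segmentation,
band-pass + notch filtering, R/P/T detection, and PR/QT/QRS measurement.
"""

import numpy as np

from beatshape.delineate import delineate_segments
from beatshape.evaluate import delineation_scores
from beatshape.preprocess import filter_segments, segment_record
from beatshape.synth import SimConfig, make_cohort

cfg = SimConfig(n_rats=1, frac_diabetic=1.0, duration_min=90.0, seed=3)
cohort = make_cohort(cfg)
rat = cohort.rats[0]

segments = segment_record(cohort.records[rat.rat_id], cohort.glucose[rat.rat_id])
offsets = {s.segment_idx: int(round(s.start_min * 60 * s.fs_hz)) for s in segments}
segments = filter_segments(segments)
table, trajectories, times = delineate_segments(segments)

print(f"{len(segments)} segments -> {len(table)} beats, "
      f"trajectory matrix {trajectories.shape}")
scores = delineation_scores(table, cohort.truth[rat.rat_id], offsets)
print(f"R-peak recall  : {100 * scores['recall']:.2f} %")
print(f"R-peak precision: {100 * scores['precision']:.2f} %")
for iv in ("pr_ms", "qt_ms", "qrs_ms"):
    print(f"median |{iv[:-3].upper()} error|: {scores[f'median_abs_err_{iv}']:.1f} ms")
print("\nmeasured intervals by glycemic stratum (median ms):")
strata = np.where(table["glucose_mg_dl"] > 70, "euglycemic",
                  np.where(table["glucose_mg_dl"] >= 15, "hypoglycemia", "severe"))
print(table.groupby(strata)[["pr_ms", "qt_ms", "qrs_ms"]].median().round(1))

# Interpretation: recall/precision near 100% and interval errors of a few
# ms; measured QT (and PR/QRS for this diabetic rat) lengthen as glucose
# falls, reproducing the planted glycemia-morphology coupling.
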