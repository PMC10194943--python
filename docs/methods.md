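# Methods

This note documents the models, algorithms and numerical choices behind
`beatshape`, in the order the pipeline runs them.

## Synthetic cohort generator

The generator emulates a single-step hyperinsulinemic hypoglycemic clamp in
adult Sprague-Dawley rats: continuous single-lead ECG at 1 kHz for 180
minutes, arterial glucose drawn every 15 minutes, and per-rat labels for
streptozotocin diabetes and death during the clamp. Cohort defaults are 91
rats with 37 diabetic and 24 dead, matching the experimental design the
package targets; labels are assigned by seeded permutation so the rounded
fractions are met exactly.

**Glucose.** Each rat starts at a euglycemic baseline (uniform 100–140
mg/dL; diabetic rats hyperglycemic at 250–350 mg/dL) and descends
exponentially (time constant = descent/3, default descent 60 min) to a
plateau at 12.5 mg/dL with clipped Gaussian noise (SD 0.8, clip ±2), so
every plateau draw stays inside the severe-hypoglycemic band 10–15 mg/dL.
The exponential shape matters: it guarantees that 15-minute draws sample
the intermediate 15–70 mg/dL range on the way down for both baseline
levels, which a linear descent from a hyperglycemic baseline would skip.

**Beats.** A beat is a sum of Gaussian bumps (P, R, S, T) with no distinct
Q wave. Geometry is derived from the interval targets: the R bump has
σ = QRS/8 so its 2σ onset sits QRS/4 before the peak; the S bump mirrors
it; the T bump spans from the S offset to the T offset (QRS onset + QT), so
the T wave is continuous with the S wave as in rat ECG; the P bump sits PR
before the QRS onset. All analytic fiducials (wave onsets/offsets at the 2σ
≙ e⁻² amplitude point) are emitted per beat as ground truth. PVC-like beats
have no P wave, a 45-ms-wide R-S complex and a discordant (inverted) T.

**Glycemia → morphology coupling.** Interval targets are piecewise linear
in glucose: (PR, QT, QRS) = (55, 68, 18) ms above 70 mg/dL, interpolating
to (80, 85, 25) ms for diabetic and (62, 80, 20) ms for non-diabetic rats
at 15 mg/dL, then prolonging further below 15 mg/dL at 0.5/0.6/0.15 ms per
mg/dL (half that for non-diabetic). The severe diabetic targets exceed all
three published flag limits while non-diabetic rats exceed only the QT
limit, so the phenotyping stage exercises both flag states; the continued
slope below 15 mg/dL keeps glucose–interval correlations defined inside the
plateau. PVC probability is zero except below 15 mg/dL (5%, or 15% for
diabetic rats that die). Heart rate is uniform per rat in 300–450 bpm with
2% lognormal beat-to-beat jitter and up to 30% RR lengthening as glucose
falls (bradycardia with deepening hypoglycemia); PVCs come 20% premature.

**Noise.** Additive baseline wander (0.1 mV at 0.3 Hz), powerline
interference (0.05 mV at 60 Hz, the configurable regional mains frequency)
and white noise (SD 0.015 mV against a 1 mV R wave). Death is a label only
by default; an optional flag truncates the recording at a random time in
the last 40% of the clamp.

All randomness flows from one integer seed through spawned NumPy
`SeedSequence`s, giving byte-identical cohorts per seed.

## Preprocessing

Recordings are segmented into half-open 15-minute windows `[t, t+15)`
anchored at glucose draw times; each segment carries the draw at its start,
and trailing partial windows are dropped. Filtering is zero-phase
(forward–backward) so fiducial timing never shifts: a band-pass Butterworth
(0.5–100 Hz, order 3) removes baseline wander and DC, and an IIR notch
(60 Hz, Q = 30) removes powerline interference. All filter parameters are
configurable; the defaults are standard rodent-ECG practice.

## Delineation

R peaks come from `scipy.signal.find_peaks` with three thresholds:
prominence (default 6 × the segment's median absolute deviation, adapting
to amplitude variation), width (≥ 1 ms), and relative height (≥ 0.4 × the
median candidate height), plus a 90 ms refractory distance that also
suppresses T waves at rat heart rates.

P search uses a window 110 down to 15 ms before R, additionally capped at
0.55 × the local RR so the previous beat's T wave can never be captured at
fast heart rates; the P is the largest local peak exceeding a 0.06 mV floor
over the window median. The wide default matters because first-degree heart
block (PR > 70 ms) places the P peak ~86 ms before R.

QRS onset and S offset are threshold crossings at e⁻² of the local peak
amplitude relative to the segment-median baseline — the same convention the
generator uses to define its analytic fiducials, and the 2σ point of a
Gaussian wave.

The T peak is the maximal deflection from baseline after the S offset
within 10–90 ms post-R (deflection magnitude, since PVC T waves are
inverted). The T offset uses a tangent-style rule: a least-squares line is
fitted to the steep section of the T downslope (30–80% of peak deflection)
and extrapolated to baseline. For a Gaussian T wave this lands at the 2σ
offset exactly, and — unlike a band-crossing rule — it stays accurate when
the T tail fuses with the next beat's P wave, which happens routinely above
~400 bpm. T analysis runs on a 40 Hz zero-phase low-passed copy of the
segment: T-wave energy lies well below 40 Hz, and the low-pass removes both
white noise and a subtle artifact of notch filtering — at rat rates a beat
harmonic falls near 60 Hz, so the notch subtracts a beat-coherent ripple
that otherwise biases slow-slope crossings by several ms.

Beat trajectories are fixed 150-sample windows (50 ms before to 100 ms
after R at 1 kHz; fits rat RR of ~130–200 ms), min-max scaled to [0, 1]
per beat (constant trajectories map to zero), with out-of-segment samples
imputed by the trajectory mean; all-missing beats are discarded with a
logged reason. Interval flags are computed from raw (pre-scaling) timing.

On synthetic cohorts at default noise this delineation reaches ~100% R
recall with median interval errors of 1–3 ms (PR, QRS) and 1–5 ms (QT);
the residual QT error is dominated by T-P fusion at the fastest heart
rates.

## Shape clustering

The dissimilarity is the discrete Fréchet distance over points
(λ·t, x(t)), computed by the standard O(n·m) dynamic program. The point
distance matrix is computed in NumPy with only correctly-rounded IEEE
operations and the coupling recursion (pure max/min) is JIT-compiled with
numba, so results are bit-for-bit reproducible and match a brute-force
recursion oracle exactly; a pure-Python fallback covers environments
without numba.

λ weights the time axis. The default is 0.1 per unit time against the
scaled amplitude: a 10 ms shift costs the full amplitude range. This
follows the longitudinal shape-clustering convention and was chosen over a
span-balancing default (amplitude range / time range ≈ 0.007 here) because
with so small a λ, monotone time warps absorb exactly the interval
prolongations the analysis needs to see — a QT-prolonged beat is nearly a
time-warp of a normal one, and planted morphology families become
indistinguishable. λ = 0 (pure shape) and span-balancing (λ = None) remain
available.

Senator reduction is Euclidean k-means (scikit-learn) over trajectory
values: senator = group mean, weight = group size; the reduction is the
identity when S ≥ n. Timepoint reduction is linear interpolation onto T'
equally spaced times. Fitting is Lloyd-style: seeded k-means++
initialization over Fréchet distances, assignment by nearest center,
center update as the weight-weighted pointwise mean (deterministic and
cheap, and identical to how cluster centers are reported downstream; a true
Fréchet mean would be neither). Convergence means assignments stopped
changing; empty clusters are re-seeded from the farthest senator; models
hitting the iteration cap (default 100) are flagged non-converged, kept in
the grid table, and excluded from selection. Five restarts per
configuration keep the best final cost, all deterministic under the seed.
Cluster ids are renumbered 1..K by descending weight. Because the center
update is a mean in value space rather than a Fréchet barycenter, the
objective is guaranteed non-increasing only across assignment steps (this
is asserted), and assignment cycling at high K is possible — mirrored in
practice by large non-converged fractions on real-scale grids.

## Model selection

Calinski-Harabasz (between/within dispersion ratio, df-scaled) and
Davies-Bouldin (mean worst-case scatter-to-separation ratio) are
implemented from their textbook formulas with weights: a senator
contributes its weight to cluster sizes and dispersions. They are
cross-checked against scikit-learn's unweighted implementations to 1e-9.
Scores are computed on the weighted senator set rather than all beats —
tractable at study scale and consistent across configurations. Degenerate
cases are explicit: zero within-cluster dispersion yields +∞ CH with a
warning; coincident centroids make DB undefined and raise.

Selection takes the converged configuration that simultaneously maximizes
CH and minimizes DB. When none dominates, the elbow is operationalized as
maximum discrete curvature: the most negative second difference of CH along
the cluster axis within each senator/timepoint series, filtered to knees
whose DB is within 10% of the global minimum, preferring higher CH and then
smaller S, K. Fewer than three converged rows fall back to argmax CH with a
warning.

## Phenotyping

Glycemic classes use the published bounds with 15 mg/dL assigned to
hypoglycemia (the printed ranges "15–70" and "< 15" force this);
euglycemic beats participate in clustering and cluster percentages but
belong to none of the eight experimental groups. Flags use strict
inequalities. χ² tests are Pearson without continuity correction on
cluster × feature count tables. The KS normality test uses the sample's own
mean and SD (no Lilliefors correction — a caveat, but immaterial at the
sample sizes involved). Median/IQR use linear-interpolation quantiles. The
heatmap matrix scales each experimental group's beat counts to percentages
over clusters (rows sum to 100) and orders rows by Ward linkage on
Euclidean distances with optimal leaf ordering. Spearman correlations use
average ranks; strength bands on |ρ| are left-closed right-open at
0.10/0.40/0.70/0.90 (the printed band edges overlap; this resolution is
ours), with the last band closed at 1.

## Problem sizes

Study-scale defaults (91 rats × 3 h ≈ 5–6 million beats, 324-model grid)
are what `configs/default.yaml` describes and are sized for a compute
cluster. The shipped tests and the acceptance script run desk-scale
versions chosen to exercise every code path: a 6-rat, 45-minute demo cohort
with a 25-minute clamp descent (so euglycemic, hypoglycemic and severe
segments all occur) and a reduced grid; a 3-rat, 90-minute cohort for
delineation scoring; and ~5000-beat planted-morphology fixtures for
clustering recovery. The demo deviates from a 30-minute recording length
precisely because a 30-minute window cannot contain all three glycemic
classes at a realistic descent rate.

## What passing tests do and do not show

The generator plants Gaussian-bump beats with known fiducials, stationary
noise, and a deterministic glycemia–morphology law. Passing recovery tests
shows the pipeline's stages are correct and internally consistent under
those assumptions. Real rat ECG adds non-Gaussian wave shapes, electrode
motion artifacts, rhythm disturbances beyond single-beat morphology
(explicitly out of scope here), drifting amplitudes, and biological
variability in the glycemia coupling — so measured accuracies on synthetic
cohorts are upper bounds, not field performance claims. The real study's
cluster compositions cannot be reproduced without the original recordings.

## Known limitations

- T-offset accuracy degrades with heart rate as T-P fusion deepens;
  above ~430 bpm the median QT error roughly doubles.
- The Fréchet k-means uses value-space mean centers, not Fréchet means;
  convergence is therefore not guaranteed and high-K models often fail to
  converge (they are reported as such).
- Senator construction and CH/DB scoring operate on the senator set; very
  small clusters inside one senator group are invisible to selection.
- The CLI and pipeline hold each rat's recording in memory (~86 MB per
  3-hour rat at 1 kHz); study-scale grids want a machine with many cores
  even though the code itself is single-threaded.
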