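"""Synthetic rat ECG cohort generator.

Emulates the experimental design of a hypoglycemic clamp study in
Sprague-Dawley rats: continuous single-lead ECG sampled at 1 kHz for three
hours while arterial glucose is clamped from a euglycemic baseline down to a
severe-hypoglycemic plateau (10-15 mg/dL), with glucose drawn every 15
minutes. Rat ECG conventions are respected: no distinct Q wave, T-wave onset
continuous with the S wave, and heart rates of roughly 300-450 bpm.

Each beat is a sum of localized Gaussian bumps (P, R, S, T) whose analytic
fiducials are known exactly, so the generator doubles as a ground-truth
oracle for the delineation stage. Interval targets (PR, QT, QRS) morph
piecewise-linearly with glucose: QT prolongs in every rat as glucose falls,
PR and QRS additionally prolong in diabetic rats, and premature-ventricular-
contraction-like beats appear only below 15 mg/dL, at an elevated rate in
diabetic rats that die.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Wave",
    "MorphologyTemplate",
    "SimConfig",
    "Rat",
    "GlucoseSeries",
    "EcgRecord",
    "Cohort",
    "make_template",
    "make_pvc_template",
    "interval_targets",
    "make_glucose_trajectory",
    "synthesize_beat",
    "synthesize_ecg",
    "make_cohort",
    "make_beat_families",
]

# Amplitude fraction defining wave onset/offset: a Gaussian bump crosses
# exp(-2) of its peak at 2 sigma from its center. The delineation stage uses
# the same fraction as its default threshold, so generator fiducials and
# measured fiducials share one convention.
ONSET_FRACTION = math.exp(-2.0)

MGDL_PER_MMOLL = 18.016  # molar mass of glucose / 10


@dataclass(frozen=True)
class Wave:
    """One localized bump: Gaussian with amplitude (mV), center and sigma (ms,
    relative to the R peak at t = 0)."""

    name: str
    amp_mv: float
    center_ms: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"wave {self.name!r}: width must be > 0")


@dataclass(frozen=True)
class MorphologyTemplate:
    """Analytic beat morphology with known fiducials and interval targets."""

    name: str
    waves: tuple[Wave, ...]
    pr_ms: float | None  # None for PVC templates (no P wave)
    qt_ms: float
    qrs_ms: float
    pvc: bool = False

    def __post_init__(self) -> None:
        centers = {w.name: w.center_ms for w in self.waves}
        if self.pvc:
            if "P" in centers:
                raise ValueError("PVC template must not carry a P wave")
        else:
            if not ("P" in centers and centers["P"] < centers["R"]):
                raise ValueError("P center must precede R center")
        if not (centers["R"] < centers["S"] < centers["T"]):
            raise ValueError("wave centers must be ordered R < S < T")
        if self.qrs_ms <= 0 or self.qt_ms <= self.qrs_ms:
            raise ValueError("need 0 < QRS < QT")

    def wave(self, name: str) -> Wave | None:
        for w in self.waves:
            if w.name == name:
                return w
        return None

    # -- analytic fiducials (ms relative to the R peak) ------------------
    @property
    def p_peak_ms(self) -> float | None:
        w = self.wave("P")
        return None if w is None else w.center_ms

    @property
    def qrs_onset_ms(self) -> float:
        return -self.qrs_ms / 4.0

    @property
    def s_offset_ms(self) -> float:
        return 3.0 * self.qrs_ms / 4.0

    @property
    def t_peak_ms(self) -> float:
        return self.wave("T").center_ms

    @property
    def t_offset_ms(self) -> float:
        return self.qrs_onset_ms + self.qt_ms

    @property
    def span_ms(self) -> tuple[float, float]:
        """(start, end) of the support, taken at 2.5 sigma per wave."""
        lo = min(w.center_ms - 2.5 * w.width_ms for w in self.waves)
        hi = max(w.center_ms + 2.5 * w.width_ms for w in self.waves)
        return lo, hi

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the beat at times ``t_ms`` (ms relative to R peak)."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        for w in self.waves:
            out += w.amp_mv * np.exp(-0.5 * ((t - w.center_ms) / w.width_ms) ** 2)
        return out


def make_template(
    pr_ms: float,
    qt_ms: float,
    qrs_ms: float,
    *,
    name: str = "normal",
    p_amp_mv: float = 0.15,
    r_amp_mv: float = 1.0,
    s_amp_mv: float = -0.4,
    t_amp_mv: float = 0.2,
    p_width_ms: float = 8.0,
) -> MorphologyTemplate:
    """Build a rat beat template that achieves the given interval targets.

    Geometry: the R bump has sigma = QRS/8 so its leading 2-sigma point (the
    QRS onset) sits QRS/4 before the R peak; the S bump mirrors it so the S
    offset sits 3·QRS/4 after the peak; the T bump fills the gap from the S
    offset to the T offset (QRS onset + QT), making the T onset continuous
    with the S wave as in rat ECGs; the P peak sits PR before the QRS onset.
    """
    sigma_rs = qrs_ms / 8.0
    qrs_onset = -qrs_ms / 4.0
    s_center = qrs_ms / 2.0
    s_offset = 3.0 * qrs_ms / 4.0
    t_offset = qrs_onset + qt_ms
    t_center = (s_offset + t_offset) / 2.0
    t_sigma = (t_offset - s_offset) / 4.0
    p_center = qrs_onset - pr_ms
    waves = (
        Wave("P", p_amp_mv, p_center, p_width_ms),
        Wave("R", r_amp_mv, 0.0, sigma_rs),
        Wave("S", s_amp_mv, s_center, sigma_rs),
        Wave("T", t_amp_mv, t_center, t_sigma),
    )
    return MorphologyTemplate(name=name, waves=waves, pr_ms=pr_ms, qt_ms=qt_ms, qrs_ms=qrs_ms)


def make_pvc_template(
    qt_ms: float = 95.0,
    qrs_ms: float = 45.0,
    *,
    name: str = "pvc",
    r_amp_mv: float = 0.9,
    s_amp_mv: float = -0.6,
    t_amp_mv: float = -0.25,
) -> MorphologyTemplate:
    """Premature-ventricular-contraction-like beat: no P wave, wide R-S
    complex, discordant (inverted) T wave."""
    sigma_rs = qrs_ms / 8.0
    qrs_onset = -qrs_ms / 4.0
    s_center = qrs_ms / 2.0
    s_offset = 3.0 * qrs_ms / 4.0
    t_offset = qrs_onset + qt_ms
    t_center = (s_offset + t_offset) / 2.0
    t_sigma = (t_offset - s_offset) / 4.0
    waves = (
        Wave("R", r_amp_mv, 0.0, sigma_rs),
        Wave("S", s_amp_mv, s_center, sigma_rs),
        Wave("T", t_amp_mv, t_center, t_sigma),
    )
    return MorphologyTemplate(name=name, waves=waves, pr_ms=None, qt_ms=qt_ms, qrs_ms=qrs_ms, pvc=True)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters. Defaults mirror the emulated experiment:
    91 rats (37 diabetic, 24 died), 3-hour recordings at 1 kHz, glucose
    drawn every 15 minutes, single-step clamp into the 10-15 mg/dL range."""

    n_rats: int = 91
    frac_diabetic: float = 37 / 91
    frac_died: float = 24 / 91
    duration_min: float = 180.0
    fs_hz: float = 1000.0
    hr_bpm: tuple[float, float] = (300.0, 450.0)
    glucose_draw_min: float = 15.0
    # clamp glucose model
    glucose_plateau_mgdl: float = 12.5
    glucose_noise_sd: float = 0.8
    clamp_descent_min: float = 60.0
    # additive noise
    wander_amp_mv: float = 0.1
    wander_freq_hz: float = 0.3
    powerline_freq_hz: float = 60.0
    powerline_amp_mv: float = 0.05
    white_noise_sd_mv: float = 0.015
    # ectopy
    pvc_prob_severe: float = 0.05
    pvc_prob_severe_died_diabetic: float = 0.15
    truncate_at_death: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.glucose_draw_min <= 0:
            raise ValueError("glucose draw cadence must be > 0")
        if abs(self.duration_min / self.glucose_draw_min % 1.0) > 1e-9:
            raise ValueError("duration_min must be divisible by glucose_draw_min")
        for frac in (self.frac_diabetic, self.frac_died):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class Rat:
    rat_id: str
    diabetic: bool
    died: bool
    base_hr_bpm: float


@dataclass(frozen=True)
class GlucoseSeries:
    """Glucose draws (mg/dL) at a fixed cadence, times in minutes."""

    times_min: np.ndarray
    values_mgdl: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.values_mgdl):
            raise ValueError("times and values must align")

    def value_at(self, t_min: float) -> float:
        """Draw value governing time ``t_min`` (step function, draw at the
        start of each interval)."""
        idx = int(np.searchsorted(self.times_min, t_min + 1e-9) - 1)
        idx = max(idx, 0)
        return float(self.values_mgdl[idx])


@dataclass
class EcgRecord:
    rat_id: str
    fs_hz: float
    signal_mv: np.ndarray
    diabetic: bool
    died: bool


@dataclass
class Cohort:
    config: SimConfig
    rats: list[Rat]
    records: dict[str, EcgRecord]
    glucose: dict[str, GlucoseSeries]
    truth: dict[str, pd.DataFrame]

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rat_id": [r.rat_id for r in self.rats],
                "diabetic": [r.diabetic for r in self.rats],
                "died": [r.died for r in self.rats],
            }
        )


# ---------------------------------------------------------------------------
# glycemia -> morphology coupling


#: Interval targets in ms at euglycemia (all rats).
BASELINE_INTERVALS = {"pr": 55.0, "qt": 68.0, "qrs": 18.0}
#: Targets reached at 15 mg/dL. Diabetic rats exceed the published
#: Sprague-Dawley upper limits (PR 70 / QT 75.9 / QRS 22 ms) on all three;
#: non-diabetic rats on QT only.
SEVERE_INTERVALS = {
    True: {"pr": 80.0, "qt": 85.0, "qrs": 25.0},
    False: {"pr": 62.0, "qt": 80.0, "qrs": 20.0},
}
#: Additional prolongation per mg/dL below 15, keeping the coupling strictly
#: monotone inside the severe plateau.
SEVERE_SLOPES = {
    True: {"pr": 0.5, "qt": 0.6, "qrs": 0.15},
    False: {"pr": 0.25, "qt": 0.3, "qrs": 0.08},
}


def interval_targets(glucose_mgdl: float, diabetic: bool) -> dict[str, float]:
    """Piecewise-linear PR/QT/QRS targets (ms) as a function of glucose."""
    g = float(glucose_mgdl)
    base = BASELINE_INTERVALS
    severe = SEVERE_INTERVALS[bool(diabetic)]
    if g >= 70.0:
        return dict(base)
    if g > 15.0:
        w = (70.0 - g) / 55.0
        return {k: base[k] + w * (severe[k] - base[k]) for k in base}
    slopes = SEVERE_SLOPES[bool(diabetic)]
    return {k: severe[k] + slopes[k] * (15.0 - g) for k in base}


def _rr_scale(glucose_mgdl: float) -> float:
    """Relative bradycardia as glucose falls (up to 1.3x at/below 15 mg/dL)."""
    w = min(max((70.0 - glucose_mgdl) / 55.0, 0.0), 1.0)
    return 1.0 + 0.3 * w


# ---------------------------------------------------------------------------
# operations


def make_glucose_trajectory(
    config: SimConfig, rat: Rat, rng: np.random.Generator | None = None
) -> GlucoseSeries:
    """Single-step clamp trajectory: euglycemic (or diabetic-hyperglycemic)
    baseline, exponential insulin-driven descent over ``clamp_descent_min``
    minutes, then a noisy plateau held inside the severe-hypoglycemic
    10-15 mg/dL band. The exponential shape means draws sample the
    intermediate hypoglycemic range (15-70 mg/dL) on the way down."""
    if config.glucose_draw_min <= 0:
        raise ValueError("glucose draw cadence must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration_min + 1e-9, config.glucose_draw_min)
    if rat.diabetic:
        baseline = rng.uniform(250.0, 350.0)
    else:
        baseline = rng.uniform(100.0, 140.0)
    target = config.glucose_plateau_mgdl
    values = np.empty_like(times)
    for i, t in enumerate(times):
        if t >= config.clamp_descent_min:
            noise = rng.normal(0.0, config.glucose_noise_sd)
            noise = float(np.clip(noise, -2.0, 2.0))
            values[i] = target + noise
        else:
            mean = target + (baseline - target) * math.exp(-3.0 * t / config.clamp_descent_min)
            noise = rng.normal(0.0, config.glucose_noise_sd * 5.0) if t > 0 else 0.0
            values[i] = max(mean + noise, target)
    return GlucoseSeries(times_min=times, values_mgdl=values)


def synthesize_beat(
    template: MorphologyTemplate, rr_ms: float, fs_hz: float
) -> tuple[np.ndarray, dict[str, int | None]]:
    """One noise-free beat of length ``rr_ms`` at ``fs_hz``.

    Returns (waveform, fiducials) where fiducial sample indices are relative
    to the waveform start; the R peak sits at the template pre-span offset.
    """
    lo, hi = template.span_ms
    if hi - lo > rr_ms:
        raise ValueError(f"template span {hi - lo:.1f} ms exceeds RR {rr_ms:.1f} ms")
    n = int(round(rr_ms * fs_hz / 1000.0))
    pre_ms = -lo
    t_ms = np.arange(n) * 1000.0 / fs_hz - pre_ms
    wave = template.waveform(t_ms)

    def _idx(ms: float | None) -> int | None:
        if ms is None:
            return None
        return int(round((ms + pre_ms) * fs_hz / 1000.0))

    fiducials = {
        "r": _idx(0.0),
        "p": _idx(template.p_peak_ms),
        "qrs_onset": _idx(template.qrs_onset_ms),
        "s_offset": _idx(template.s_offset_ms),
        "t_peak": _idx(template.t_peak_ms),
        "t_offset": _idx(template.t_offset_ms),
    }
    return wave, fiducials


def _quantize(x: float, step: float = 0.25) -> float:
    return round(x / step) * step


def synthesize_ecg(
    rat: Rat,
    glucose: GlucoseSeries,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[EcgRecord, pd.DataFrame]:
    """Full recording for one rat plus its per-beat ground truth.

    Beats are superposed additively on a zero baseline at RR intervals drawn
    from the rat's base heart rate (with glycemia-dependent slowing and small
    beat-to-beat jitter); baseline wander, powerline interference and white
    noise are added afterwards.
    """
    if glucose.times_min[-1] + config.glucose_draw_min < config.duration_min - 1e-9:
        raise ValueError("glucose series does not cover the recording")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    n_samples = int(round(config.duration_min * 60.0 * fs))
    signal = np.zeros(n_samples)
    base_rr_ms = 60000.0 / rat.base_hr_bpm

    death_min = config.duration_min
    if config.truncate_at_death and rat.died:
        death_min = rng.uniform(0.6, 1.0) * config.duration_min

    template_cache: dict[tuple, MorphologyTemplate] = {}
    rows: list[dict] = []
    t_ms = base_rr_ms  # leave room for the first beat's P wave
    beat_idx = 0
    while True:
        t_min = t_ms / 60000.0
        if t_min >= min(config.duration_min, death_min):
            break
        g = glucose.value_at(t_min)
        severe = g < 15.0
        p_pvc = 0.0
        if severe:
            if rat.diabetic and rat.died:
                p_pvc = config.pvc_prob_severe_died_diabetic
            else:
                p_pvc = config.pvc_prob_severe
        is_pvc = rng.random() < p_pvc
        if is_pvc:
            key = ("pvc",)
            tmpl = template_cache.get(key)
            if tmpl is None:
                tmpl = make_pvc_template()
                template_cache[key] = tmpl
        else:
            tg = interval_targets(g, rat.diabetic)
            key = (_quantize(tg["pr"]), _quantize(tg["qt"]), _quantize(tg["qrs"]))
            tmpl = template_cache.get(key)
            if tmpl is None:
                tmpl = make_template(key[0], key[1], key[2])
                template_cache[key] = tmpl

        r_idx = int(round(t_ms * fs / 1000.0))
        lo, hi = tmpl.span_ms
        i0 = int(np.floor((t_ms + lo - 5.0) * fs / 1000.0))
        i1 = int(np.ceil((t_ms + hi + 5.0) * fs / 1000.0))
        i0c, i1c = max(i0, 0), min(i1, n_samples)
        if i1c > i0c:
            local_t = np.arange(i0c, i1c) * 1000.0 / fs - t_ms
            signal[i0c:i1c] += tmpl.waveform(local_t)
        # snap the truth R index to the discrete-grid maximum (beats are
        # placed at fractional-sample times)
        if 1 <= r_idx < n_samples - 1:
            r_idx += int(np.argmax(signal[r_idx - 1 : r_idx + 2])) - 1

        def _abs_idx(ms: float | None) -> float:
            if ms is None:
                return np.nan
            return round((t_ms + ms) * fs / 1000.0)

        rows.append(
            {
                "rat_id": rat.rat_id,
                "beat_idx": beat_idx,
                "r_index": r_idx,
                "p_index": _abs_idx(tmpl.p_peak_ms),
                "qrs_onset_index": _abs_idx(tmpl.qrs_onset_ms),
                "s_offset_index": _abs_idx(tmpl.s_offset_ms),
                "t_offset_index": _abs_idx(tmpl.t_offset_ms),
                "pr_ms": np.nan if tmpl.pr_ms is None else tmpl.pr_ms,
                "qt_ms": tmpl.qt_ms,
                "qrs_ms": tmpl.qrs_ms,
                "template": tmpl.name,
                "glucose_mg_dl": g,
            }
        )
        beat_idx += 1

        rr = base_rr_ms * _rr_scale(g) * float(rng.lognormal(0.0, 0.02))
        if is_pvc:
            rr *= 0.8  # premature
        t_ms += rr

    # additive noise
    t_s = np.arange(n_samples) / fs
    if config.wander_amp_mv > 0:
        signal += config.wander_amp_mv * np.sin(
            2.0 * np.pi * config.wander_freq_hz * t_s + rng.uniform(0, 2 * np.pi)
        )
    if config.powerline_amp_mv > 0:
        signal += config.powerline_amp_mv * np.sin(
            2.0 * np.pi * config.powerline_freq_hz * t_s + rng.uniform(0, 2 * np.pi)
        )
    if config.white_noise_sd_mv > 0:
        signal += rng.normal(0.0, config.white_noise_sd_mv, n_samples)

    truth = pd.DataFrame(rows)
    record = EcgRecord(
        rat_id=rat.rat_id, fs_hz=fs, signal_mv=signal, diabetic=rat.diabetic, died=rat.died
    )
    return record, truth


def make_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort: rats with diabetic/died labels matching the
    configured fractions exactly (rounded), one record + glucose trajectory +
    ground-truth table per rat. Deterministic under ``config.seed``."""
    if config.n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    root = np.random.SeedSequence(config.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    n = config.n_rats
    n_diab = int(round(config.frac_diabetic * n))
    n_died = int(round(config.frac_died * n))
    diabetic = np.zeros(n, dtype=bool)
    diabetic[label_rng.permutation(n)[:n_diab]] = True
    died = np.zeros(n, dtype=bool)
    died[label_rng.permutation(n)[:n_died]] = True

    rats: list[Rat] = []
    records: dict[str, EcgRecord] = {}
    glucose: dict[str, GlucoseSeries] = {}
    truth: dict[str, pd.DataFrame] = {}
    rat_seeds = root.spawn(n + 1)[1:]
    for i in range(n):
        rng = np.random.default_rng(rat_seeds[i])
        rat = Rat(
            rat_id=f"rat{i + 1:03d}",
            diabetic=bool(diabetic[i]),
            died=bool(died[i]),
            base_hr_bpm=float(rng.uniform(*config.hr_bpm)),
        )
        gs = make_glucose_trajectory(config, rat, rng)
        rec, tr = synthesize_ecg(rat, gs, config, rng)
        rats.append(rat)
        records[rat.rat_id] = rec
        glucose[rat.rat_id] = gs
        truth[rat.rat_id] = tr
    return Cohort(config=config, rats=rats, records=records, glucose=glucose, truth=truth)


def make_beat_families(
    templates: list[MorphologyTemplate] | None = None,
    n_per_family: int | list[int] = 1000,
    noise_sd: float = 0.05,
    seed: int = 0,
    *,
    pre_ms: float = 50.0,
    post_ms: float = 100.0,
    fs_hz: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted-truth clustering fixture: min-max-scaled beat trajectories
    drawn from k morphology families with additive white noise.

    Returns (trajectories (n, T), times_ms (T,), family labels (n,)).
    Defaults plant the three study-relevant morphologies: normal,
    QT-prolonged, and PVC-like.
    """
    if templates is None:
        templates = [
            make_template(55.0, 68.0, 18.0, name="normal"),
            make_template(70.0, 85.0, 20.0, name="qt_prolonged"),
            make_pvc_template(),
        ]
    if isinstance(n_per_family, int):
        counts = [n_per_family] * len(templates)
    else:
        counts = list(n_per_family)
    rng = np.random.default_rng(seed)
    n_t = int(round((pre_ms + post_ms) * fs_hz / 1000.0))
    times = np.arange(n_t) * 1000.0 / fs_hz - pre_ms
    trajs, labels = [], []
    for fam, (tmpl, cnt) in enumerate(zip(templates, counts)):
        base = tmpl.waveform(times)
        rng_ = base.max() - base.min()
        scaled = (base - base.min()) / rng_ if rng_ > 0 else np.zeros_like(base)
        block = scaled[None, :] + rng.normal(0.0, noise_sd, (cnt, n_t))
        trajs.append(block)
        labels.extend([fam] * cnt)
    X = np.vstack(trajs)
    y = np.asarray(labels)
    perm = rng.permutation(len(y))
    return X[perm], times, y[perm]
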