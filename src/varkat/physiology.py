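"""Organism-level physiology metrics.

Zebrafish embryonic cardiac function from ellipse-fit ventricle traces
(heart rate, spheroid volumes, stroke volume, cardiac output, shortening
fraction, fractional area change, ejection fraction), cardinal-vein red
blood cell velocity, larval locomotor summaries from x/y tracks, mouse
inverted-screen scoring, and adult 6-minute-walk reference distances.

The ventricular volume uses the prolate-spheroid formula V = 4/3*pi*a*b^2
applied verbatim to the supplied long (a) and short (b) axis values; an
optional semi-axis mode divides by 8 (pi*a*b^2/6). The interpretation
cancels in all fractional metrics (SF, FAC, EF) and in relative
comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_FPS = 150.0
RBC_WINDOW_FRAMES = 10
INACTIVITY_THRESHOLD_MM_S = 2.0
SMALL_MOVEMENT_MM_S = 10.0
HIGH_SPEED_MM_S = 20.0  # package default; not a published threshold
BIN_LENGTH_S = 30.0
INVERTED_SCREEN_CAP_S = 180.0
INVERTED_SCREEN_TRIALS = 6


# ---------------------------------------------------------------------------
# Cardiac function
# ---------------------------------------------------------------------------

@dataclass
class VentricleTrace:
    """Per-frame ventricle geometry: long axis a, short axis b, area A
    (consistent length units), with annotated diastole/systole frames."""

    long_axis: Sequence[float]
    short_axis: Sequence[float]
    area: Sequence[float]
    fps: float = DEFAULT_FPS
    diastole_frames: Sequence[int] = field(default_factory=list)
    systole_frames: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        a = np.asarray(self.long_axis, float)
        b = np.asarray(self.short_axis, float)
        if np.any(b <= 0) or np.any(a < b):
            raise ValueError("require long axis >= short axis > 0 per frame")


@dataclass
class CardiacMetrics:
    HR_bpm: float
    EDV: float
    ESV: float
    SV: float
    CO_per_min: float
    SF_pct: float
    FAC_pct: float
    EF_pct: float
    per_beat_EDV: list[float] = field(default_factory=list)
    per_beat_ESV: list[float] = field(default_factory=list)
    valid: bool = True


def spheroid_volume(a: float, b: float, semi_axes: bool = False) -> float:
    """Prolate-spheroid ventricular volume V = 4/3*pi*a*b^2 from the long
    (a) and short (b) axis. ``semi_axes=True`` treats a, b as full lengths
    and halves them (V = pi*a*b^2/6)."""
    if a <= 0 or b <= 0:
        raise ValueError("axes must be positive")
    v = 4.0 / 3.0 * math.pi * a * b * b
    return v / 8.0 if semi_axes else v


def heart_rate(trace: VentricleTrace) -> float:
    """Heart rate in bpm from annotated beats: 60 / mean inter-beat
    interval, averaged over successive three-beat triplets."""
    frames = np.asarray(trace.diastole_frames, float)
    if len(frames) < 3:
        raise ValueError("need >= 3 annotated beats")
    intervals = np.diff(frames) / trace.fps  # seconds
    # triplicate measurement: mean interval within consecutive triplets
    trip = [intervals[i : i + 2].mean() for i in range(0, len(intervals) - 1, 2)]
    return float(np.mean([60.0 / t for t in trip]))


def cardiac_metrics(trace: VentricleTrace, semi_axes: bool = False) -> CardiacMetrics:
    """Per-beat spheroid volumes at annotated diastole/systole frames,
    summarised as triplicate means.

    SV = EDV - ESV; CO = HR * SV; SF = (Ld - Ls)/Ld * 100;
    FAC = (Ad - As)/Ad * 100; EF = (EDV - ESV)/EDV * 100.
    A trace where ESV exceeds EDV in more than half the beats is flagged
    invalid.
    """
    dia = list(trace.diastole_frames)
    sys_ = list(trace.systole_frames)
    if len(dia) < 3 or len(sys_) < 3:
        raise ValueError("need >= 3 annotated beats with diastole and systole")
    n = min(len(dia), len(sys_))
    a = np.asarray(trace.long_axis, float)
    b = np.asarray(trace.short_axis, float)
    area = np.asarray(trace.area, float)

    edv = [spheroid_volume(a[i], b[i], semi_axes) for i in dia[:n]]
    esv = [spheroid_volume(a[i], b[i], semi_axes) for i in sys_[:n]]
    bad = sum(1 for e, s in zip(edv, esv) if s > e)
    valid = bad <= n / 2
    if not valid:
        warnings.warn("ESV > EDV in more than half the beats; trace flagged invalid")

    EDV = float(np.mean(edv))
    ESV = float(np.mean(esv))
    SV = EDV - ESV
    hr = heart_rate(trace)
    Ld = float(np.mean(a[dia[:n]]))
    Ls = float(np.mean(a[sys_[:n]]))
    Ad = float(np.mean(area[dia[:n]]))
    As = float(np.mean(area[sys_[:n]]))
    return CardiacMetrics(
        HR_bpm=hr,
        EDV=EDV,
        ESV=ESV,
        SV=SV,
        CO_per_min=hr * SV,
        SF_pct=(Ld - Ls) / Ld * 100.0,
        FAC_pct=(Ad - As) / Ad * 100.0,
        EF_pct=(EDV - ESV) / EDV * 100.0,
        per_beat_EDV=edv,
        per_beat_ESV=esv,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# RBC velocity
# ---------------------------------------------------------------------------

def rbc_velocity(
    cell_tracks: Sequence[Sequence[tuple[float, float]]],
    fps: float = DEFAULT_FPS,
    window_frames: int = RBC_WINDOW_FRAMES,
) -> float:
    """Mean erythrocyte velocity (mm/s) for one fish.

    Each cell track is a sequence of >= ``window_frames`` consecutive (x, y)
    positions in mm; per-cell velocity is the mean frame-to-frame
    displacement times fps over the first ``window_frames`` frames, and the
    per-fish value averages the (conventionally three) cells.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    per_cell = []
    for track in cell_tracks:
        if len(track) < window_frames:
            raise ValueError(
                f"track of {len(track)} frames; need >= {window_frames} consecutive"
            )
        pts = np.asarray(track[:window_frames], float)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        per_cell.append(float(steps.mean() * fps))
    if not per_cell:
        raise ValueError("no cell tracks supplied")
    return float(np.mean(per_cell))


# ---------------------------------------------------------------------------
# Locomotor summary
# ---------------------------------------------------------------------------

@dataclass
class LocomotorSummary:
    bin_edges_s: list[float]
    bin_distance_mm: list[float]
    bin_moving_time_s: list[float]
    total_distance_mm: float
    total_moving_time_s: float
    small_movement_time_s: float
    high_speed_time_s: float


def locomotor_summary(
    x_mm: Sequence[float],
    y_mm: Sequence[float],
    timestamps_s: Sequence[float],
    bin_length_s: float = BIN_LENGTH_S,
    inactivity_threshold: float = INACTIVITY_THRESHOLD_MM_S,
    small_threshold: float = SMALL_MOVEMENT_MM_S,
    high_speed_threshold: float = HIGH_SPEED_MM_S,
) -> LocomotorSummary:
    """Summarise one larva's x/y track into fixed integration bins.

    Frame-to-frame speeds below the inactivity threshold (default 2 mm/s,
    removing system noise) count as inactive and contribute no distance.
    Moving frames are classified small (< 10 mm/s) or high-speed
    (>= ``high_speed_threshold``). Distances and moving times are
    aggregated per bin (default 30 s) and totalled.
    """
    t = np.asarray(timestamps_s, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    duration = t[-1] - t[0]
    if bin_length_s > duration:
        raise ValueError("integration bin longer than the recording")
    x = np.asarray(x_mm, float)
    y = np.asarray(y_mm, float)
    dt = np.diff(t)
    step = np.hypot(np.diff(x), np.diff(y))
    speed = step / dt
    moving = speed >= inactivity_threshold
    small = moving & (speed < small_threshold)
    high = speed >= high_speed_threshold

    n_bins = int(math.ceil(duration / bin_length_s - 1e-9))
    edges = [t[0] + i * bin_length_s for i in range(n_bins + 1)]
    mid = t[:-1]  # attribute each step to its starting frame
    bin_idx = np.clip(((mid - t[0]) / bin_length_s).astype(int), 0, n_bins - 1)

    bin_dist = np.zeros(n_bins)
    bin_time = np.zeros(n_bins)
    np.add.at(bin_dist, bin_idx[moving], step[moving])
    np.add.at(bin_time, bin_idx[moving], dt[moving])
    return LocomotorSummary(
        bin_edges_s=edges,
        bin_distance_mm=bin_dist.tolist(),
        bin_moving_time_s=bin_time.tolist(),
        total_distance_mm=float(bin_dist.sum()),
        total_moving_time_s=float(bin_time.sum()),
        small_movement_time_s=float(dt[small].sum()),
        high_speed_time_s=float(dt[high].sum()),
    )


# ---------------------------------------------------------------------------
# Inverted screen
# ---------------------------------------------------------------------------

def inverted_screen_score(
    trial_times_s: Sequence[float],
    n_trials: int = INVERTED_SCREEN_TRIALS,
    cap_s: float = INVERTED_SCREEN_CAP_S,
) -> dict:
    """Cap each hang time at ``cap_s`` (mice removed at the full duration
    are assigned the cap) and sum across trials."""
    if any(t < 0 for t in trial_times_s):
        raise ValueError("trial times must be nonnegative")
    if len(trial_times_s) != n_trials:
        warnings.warn(
            f"expected {n_trials} trials, got {len(trial_times_s)}; proceeding"
        )
    capped = [min(t, cap_s) for t in trial_times_s]
    return {"per_trial_s": capped, "cumulative_s": float(sum(capped))}


# ---------------------------------------------------------------------------
# 6-minute-walk reference
# ---------------------------------------------------------------------------

def reference_6mwd(sex: str, height_cm: float, age_y: float, weight_kg: float) -> float:
    """Adult 6-minute-walk reference distance (m), Enright-Sherrill
    equations:

    men:   6MWD = 7.57*height - 5.02*age - 1.76*weight - 309
    women: 6MWD = 2.11*height - 2.29*weight - 5.78*age + 667
    """
    if height_cm <= 0 or age_y <= 0 or weight_kg <= 0:
        raise ValueError("anthropometrics must be positive")
    s = sex.lower()
    if s in ("m", "male", "man", "men"):
        return 7.57 * height_cm - 5.02 * age_y - 1.76 * weight_kg - 309.0
    if s in ("f", "female", "woman", "women"):
        return 2.11 * height_cm - 2.29 * weight_kg - 5.78 * age_y + 667.0
    raise ValueError(f"unknown sex {sex!r}")
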