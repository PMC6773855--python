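"""Synthetic functional-assay data generated from the analysis models.

Each simulator draws from the same closed form its analysis counterpart
fits — cumulative efflux ``1 - exp(-(k1 + k2) t)``, the Hill inhibition
curve, prolate-spheroid ventricle geometry, a bounded-speed locomotor walk
— plus stated noise, so that noiseless output lies exactly on the model and
fits can be validated by round-trip recovery against the emitted truth
ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..assays import (
    DEFAULT_TIMEPOINTS,
    EffluxTimeSeries,
    ExpressionMeasurement,
    hill_current,
)
from ..physiology import VentricleTrace


@dataclass
class EffluxSimSpec:
    k1: float = 0.01  # per-minute background rate (GFP-only cells)
    k2: float = 0.10  # per-minute channel-dependent rate
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS
    total_counts: float = 50_000.0
    count_noise_scale: float = 1.0  # 0 = noiseless; 1 = Poisson counting noise
    n_wells: int = 6

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be nonnegative")


@dataclass
class DoseResponseSimSpec:
    IC50: float = 100.0  # ATP concentration units (uM)
    H: float = 1.3
    Imin: float = 0.0
    concentrations: Sequence[float] = (1.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 10_000.0)
    noise_sd: float = 0.03
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.IC50 <= 0 or self.H <= 0:
            raise ValueError("IC50 and H must be positive")
        if not 0.0 <= self.Imin <= 1.0:
            raise ValueError("Imin must lie in [0, 1]")


@dataclass
class VentricleSimSpec:
    # 5-dpf zebrafish scale, lengths in um
    a_diastole: float = 120.0
    b_diastole: float = 80.0
    a_systole: float = 100.0
    b_systole: float = 60.0
    bpm: float = 180.0
    fps: float = 150.0
    duration_s: float = 10.0
    noise_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.bpm <= 0:
            raise ValueError("fps and bpm must be positive")


@dataclass
class TrackSimSpec:
    speed_mean_mm_s: float = 5.0
    speed_sd_mm_s: float = 0.0
    moving_fraction: float = 1.0  # fraction of frames above noise threshold
    duration_s: float = 300.0
    fps: float = 25.0


@dataclass
class AssaySimSpec:
    efflux: EffluxSimSpec = field(default_factory=EffluxSimSpec)
    dose_response: DoseResponseSimSpec = field(default_factory=DoseResponseSimSpec)
    ventricle: VentricleSimSpec = field(default_factory=VentricleSimSpec)
    track: TrackSimSpec = field(default_factory=TrackSimSpec)
    seed: int = 0


# ---------------------------------------------------------------------------
# Efflux
# ---------------------------------------------------------------------------

def simulate_efflux(
    spec: EffluxSimSpec, seed: int = 0, background_only: bool = False
) -> tuple[list[EffluxTimeSeries], dict]:
    """Per-well released counts at the assay timepoints.

    The noiseless cumulative fraction at time t is
    ``1 - exp(-(k1 + k2) t)`` (k2 = 0 for GFP-only wells); counting noise is
    Poisson with the interval expectation scaled by ``count_noise_scale``.
    """
    rng = np.random.default_rng(seed)
    k = spec.k1 + (0.0 if background_only else spec.k2)
    t = np.asarray(spec.timepoints, dtype=float)
    frac = 1.0 - np.exp(-k * t)
    increments = np.diff(np.concatenate([[0.0], frac])) * spec.total_counts
    wells = []
    for w in range(spec.n_wells):
        if spec.count_noise_scale == 0:
            released = increments.copy()
        else:
            lam = increments / spec.count_noise_scale
            released = rng.poisson(np.clip(lam, 0, None)) * spec.count_noise_scale
        lysate = max(spec.total_counts - released.sum(), 0.0)
        wells.append(
            EffluxTimeSeries(
                timepoints=tuple(t),
                released_counts=released.tolist(),
                lysate_counts=float(lysate),
                condition="gfp" if background_only else "channel",
            )
        )
    truth = {"k1": spec.k1, "k2": 0.0 if background_only else spec.k2, "seed": seed}
    return wells, truth


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

def simulate_dose_response(
    spec: DoseResponseSimSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """(concentrations, normalized currents, truth); currents lie on the
    Hill curve plus Gaussian noise of sd ``noise_sd``."""
    rng = np.random.default_rng(seed)
    x = np.tile(np.asarray(spec.concentrations, dtype=float), spec.n_replicates)
    y = hill_current(x, spec.Imin, spec.IC50, spec.H)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    truth = {"IC50": spec.IC50, "H": spec.H, "Imin": spec.Imin, "seed": seed}
    return x, y, truth


# ---------------------------------------------------------------------------
# Ventricle trace
# ---------------------------------------------------------------------------

def simulate_ventricle_trace(
    spec: VentricleSimSpec, seed: int = 0
) -> tuple[VentricleTrace, dict]:
    """Sinusoidal beat-to-beat ventricle geometry.

    The beat period is rounded to a whole number of frames (the truth
    ledger reports the implied exact heart rate); diastole falls on the
    first frame of each beat and systole half a period later, so annotated
    frames carry exactly the planted axis values. The per-frame area is the
    ellipse area pi/4*a*b.
    """
    rng = np.random.default_rng(seed)
    period_frames = max(int(round(spec.fps * 60.0 / spec.bpm)), 2)
    if period_frames % 2:
        period_frames += 1  # keep systole exactly mid-beat
    true_bpm = 60.0 * spec.fps / period_frames
    n_frames = int(spec.duration_s * spec.fps)
    phase = 2.0 * math.pi * np.arange(n_frames) / period_frames
    w = 0.5 * (1.0 + np.cos(phase))  # 1 at diastole, 0 at systole
    a = spec.a_systole + (spec.a_diastole - spec.a_systole) * w
    b = spec.b_systole + (spec.b_diastole - spec.b_systole) * w
    if spec.noise_frac > 0:
        a = a * (1.0 + rng.normal(0, spec.noise_frac, n_frames))
        b = b * (1.0 + rng.normal(0, spec.noise_frac, n_frames))
        b = np.minimum(b, a - 1e-9)
    area = math.pi / 4.0 * a * b
    diastole = list(range(0, n_frames, period_frames))
    systole = [f + period_frames // 2 for f in diastole if f + period_frames // 2 < n_frames]
    n_beats = min(len(diastole), len(systole))
    trace = VentricleTrace(
        long_axis=a.tolist(),
        short_axis=b.tolist(),
        area=area.tolist(),
        fps=spec.fps,
        diastole_frames=diastole[:n_beats],
        systole_frames=systole[:n_beats],
    )
    edv = 4.0 / 3.0 * math.pi * spec.a_diastole * spec.b_diastole**2
    esv = 4.0 / 3.0 * math.pi * spec.a_systole * spec.b_systole**2
    ad = math.pi / 4.0 * spec.a_diastole * spec.b_diastole
    as_ = math.pi / 4.0 * spec.a_systole * spec.b_systole
    truth = {
        "HR_bpm": true_bpm,
        "EDV": edv,
        "ESV": esv,
        "SV": edv - esv,
        "CO_per_min": true_bpm * (edv - esv),
        "SF_pct": (spec.a_diastole - spec.a_systole) / spec.a_diastole * 100.0,
        "FAC_pct": (ad - as_) / ad * 100.0,
        "EF_pct": (edv - esv) / edv * 100.0,
        "seed": seed,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Locomotor / RBC tracks
# ---------------------------------------------------------------------------

def simulate_track(
    spec: TrackSimSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """(x_mm, y_mm, timestamps_s, truth): a random-heading walk whose
    per-frame speed is ``speed_mean`` + Gaussian noise (truncated at 0)
    during moving frames and 0 during still frames."""
    rng = np.random.default_rng(seed)
    n = int(spec.duration_s * spec.fps)
    dt = 1.0 / spec.fps
    moving = rng.random(n) < spec.moving_fraction
    speeds = np.where(
        moving,
        np.clip(rng.normal(spec.speed_mean_mm_s, spec.speed_sd_mm_s, n), 0, None),
        0.0,
    )
    headings = rng.uniform(0, 2 * math.pi, n)
    dx = speeds * dt * np.cos(headings)
    dy = speeds * dt * np.sin(headings)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    t = np.arange(n + 1) * dt
    truth = {
        "total_distance_mm": float((speeds * dt)[moving].sum()),
        "moving_time_s": float(moving.sum() * dt),
        "speed_mean_mm_s": spec.speed_mean_mm_s,
        "seed": seed,
    }
    return x, y, t, truth


def simulate_rbc_tracks(
    velocity_mm_s: float,
    n_cells: int = 3,
    n_frames: int = 10,
    fps: float = 150.0,
    jitter_mm: float = 0.0,
    seed: int = 0,
) -> tuple[list[list[tuple[float, float]]], dict]:
    """Constant-velocity erythrocyte tracks along the vein axis with
    optional positional jitter."""
    rng = np.random.default_rng(seed)
    step = velocity_mm_s / fps
    tracks = []
    for _ in range(n_cells):
        xs = np.arange(n_frames) * step + rng.uniform(0, 0.05)
        ys = rng.normal(0, jitter_mm, n_frames) if jitter_mm > 0 else np.zeros(n_frames)
        tracks.append(list(zip(xs.tolist(), ys.tolist())))
    return tracks, {"velocity_mm_s": velocity_mm_s, "seed": seed}


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    fold_change: float = 0.25,
    n_wt_pools: int = 3,
    n_mut_pools: int = 4,
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[ExpressionMeasurement], dict]:
    """Ct values for target and reference genes in WT and mutant pools,
    such that the noiseless Pfaffl/2^-ddCt ratio of each mutant pool equals
    ``fold_change``. Pools of 60 pooled larvae are emulated as single
    measurements."""
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    rng = np.random.default_rng(seed)
    delta_ct = -math.log2(fold_change)  # extra cycles needed by the mutant
    out = []
    for i in range(n_wt_pools):
        out.append(
            ExpressionMeasurement(
                sample=f"WT{i + 1}",
                ct_target=base_ct_target + float(rng.normal(0, ct_noise_sd)),
                ct_reference=base_ct_reference + float(rng.normal(0, ct_noise_sd)),
                is_wildtype=True,
            )
        )
    for i in range(n_mut_pools):
        out.append(
            ExpressionMeasurement(
                sample=f"MUT{i + 1}",
                ct_target=base_ct_target + delta_ct + float(rng.normal(0, ct_noise_sd)),
                ct_reference=base_ct_reference + float(rng.normal(0, ct_noise_sd)),
                is_wildtype=False,
            )
        )
    return out, {"fold_change": fold_change, "seed": seed}
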