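"""Quantitative analysis of K_ATP channel functional assays.

Covers four measurements used to characterise channel loss-of-function:

* Cumulative radioactive rubidium (86Rb+) efflux and its decomposition into
  a background rate constant k1 (GFP-only cells, ``Efflux = 1 - exp(-k1 t)``)
  and a channel-dependent rate constant k2 (channel-expressing cells,
  ``Efflux = 1 - exp(-(k1 + k2) t)`` with k1 held fixed). Active-channel
  number is taken proportional to k2. Because efflux diverges from a
  mono-exponential at later times, rates are fitted on the early window
  (2.5-12.5 min) only.
* ATP dose-response of channel current, fitted with a Hill curve
  ``I = Imin + (Imax - Imin) / (1 + ([X]/IC50)^H)`` where the basal current
  in nucleotide-free solution defines Imax = 1.
* K_ATP current from excised-patch records: the difference between the
  current in nucleotide-free solution and at a fully inhibiting ATP
  concentration.
* Relative qPCR expression by the efficiency-corrected (Pfaffl) ratio,
  reducing to 2^-ddCt when both efficiencies are 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

DEFAULT_TIMEPOINTS = (2.5, 5.0, 12.5, 22.5, 37.5)
FIT_WINDOW_MIN = (2.5, 12.5)


# ---------------------------------------------------------------------------
# Efflux
# ---------------------------------------------------------------------------

@dataclass
class EffluxTimeSeries:
    """Per-well released counts at fixed timepoints plus final lysate counts."""

    timepoints: Sequence[float]
    released_counts: Sequence[float]
    lysate_counts: float
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.released_counts):
            raise ValueError("one released count per timepoint required")
        if any(c < 0 for c in self.released_counts) or self.lysate_counts < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class EffluxRates:
    k1: float
    k2: Optional[float] = None
    fit_window: tuple[float, float] = FIT_WINDOW_MIN
    residual_norm: float = 0.0


def cumulative_efflux(series: EffluxTimeSeries) -> np.ndarray:
    """Cumulative fraction released at each timepoint:
    fraction(t_i) = sum of released counts up to t_i / (all released + lysate)."""
    released = np.asarray(series.released_counts, dtype=float)
    total = released.sum() + series.lysate_counts
    if total <= 0:
        raise ValueError("total counts are zero; cannot form fractions")
    return np.cumsum(released) / total


def _pooled_window_points(
    series_set: Iterable[EffluxTimeSeries], window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    ts, fs = [], []
    for s in series_set:
        frac = cumulative_efflux(s)
        for t, f in zip(s.timepoints, frac):
            if window[0] <= t <= window[1]:
                ts.append(t)
                fs.append(f)
    t = np.asarray(ts, dtype=float)
    f = np.asarray(fs, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 timepoints inside the fit window")
    return t, f


def _rate_init(t: np.ndarray, f: np.ndarray) -> float:
    """Log-linearised initial rate: mean of -ln(1 - f)/t over usable points."""
    ok = (f < 1.0) & (t > 0)
    if not ok.any():
        return 0.1
    return float(np.clip(np.mean(-np.log1p(-f[ok]) / t[ok]), 1e-8, None))


def _prefer_boundary(resid, k_hat: float) -> float:
    """Take the k = 0 boundary solution when it fits at least as well as
    the interior optimum (the optimizer cannot land exactly on a bound)."""
    if np.sum(resid([0.0]) ** 2) <= np.sum(resid([k_hat]) ** 2):
        return 0.0
    return k_hat


def fit_background_rate(
    gfp_series: Iterable[EffluxTimeSeries],
    window: tuple[float, float] = FIT_WINDOW_MIN,
) -> EffluxRates:
    """Fit the background efflux rate k1 to pooled GFP-only wells on the
    early-time window by bounded least squares of 1 - exp(-k1 t)."""
    t, f = _pooled_window_points(gfp_series, window)
    if np.all(f >= 1.0):
        raise ValueError("degenerate data: all fractions >= 1")

    def resid(k):
        return 1.0 - np.exp(-k[0] * t) - f

    sol = optimize.least_squares(
        resid, x0=[_rate_init(t, f)], bounds=([0.0], [np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    k1 = _prefer_boundary(resid, float(sol.x[0]))
    return EffluxRates(
        k1=k1, fit_window=window, residual_norm=float(np.linalg.norm(resid([k1])))
    )


def fit_katp_rate(
    channel_series: Iterable[EffluxTimeSeries],
    k1: float,
    window: tuple[float, float] = FIT_WINDOW_MIN,
) -> EffluxRates:
    """Fit the channel-dependent rate k2 with the background k1 held fixed:
    least squares of 1 - exp(-(k1 + k2) t) on the early-time window."""
    if k1 < 0:
        raise ValueError("k1 must be nonnegative")
    t, f = _pooled_window_points(channel_series, window)

    def resid(k):
        return 1.0 - np.exp(-(k1 + k[0]) * t) - f

    x0 = max(_rate_init(t, f) - k1, 1e-8)
    sol = optimize.least_squares(
        resid, x0=[x0], bounds=([0.0], [np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    k2 = _prefer_boundary(resid, float(sol.x[0]))
    return EffluxRates(
        k1=k1, k2=k2, fit_window=window,
        residual_norm=float(np.linalg.norm(resid([k2]))),
    )


# ---------------------------------------------------------------------------
# Hill dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    concentrations: np.ndarray
    normalized_currents: np.ndarray
    Imin: float
    IC50: float
    H: float
    Imax: float = 1.0
    converged: bool = True
    residual_norm: float = 0.0


def hill_current(x, Imin, IC50, H, Imax=1.0):
    """Hill inhibition curve: Imin + (Imax - Imin) / (1 + (x/IC50)^H)."""
    x = np.asarray(x, dtype=float)
    return Imin + (Imax - Imin) / (1.0 + (x / IC50) ** H)


def normalize_and_fit_hill(
    concentrations: Sequence[float],
    currents: Sequence[float],
    basal_current: float = 1.0,
) -> DoseResponse:
    """Normalize currents to the basal (nucleotide-free) current, fixing
    Imax = 1, and fit Imin, IC50 and H by bounded least squares.

    Initialisation: IC50 at the geometric mean of the concentration range,
    H = 1, Imin at the smallest observed normalized current (clipped to
    [0, 1]).
    """
    x = np.asarray(concentrations, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if basal_current <= 0:
        raise ValueError("basal current must be positive")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    y = np.asarray(currents, dtype=float) / basal_current

    ic50_0 = float(np.exp(np.mean(np.log([x.min(), x.max()]))))
    imin_0 = float(np.clip(y.min(), 0.0, 1.0))

    def resid(p):
        return hill_current(x, p[0], p[1], p[2]) - y

    sol = optimize.least_squares(
        resid,
        x0=[imin_0, ic50_0, 1.0],
        bounds=([0.0, 1e-12, 1e-6], [1.0, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    # warn (not fail) when the data are not a decreasing dose-response
    order = np.argsort(x)
    converged = bool(sol.success)
    if np.any(np.diff(y[order]) > 0.2):
        warnings.warn("dose-response data non-monotone beyond noise tolerance")
        converged = False
    return DoseResponse(
        concentrations=x,
        normalized_currents=y,
        Imin=float(sol.x[0]),
        IC50=float(sol.x[1]),
        H=float(sol.x[2]),
        converged=converged,
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


# ---------------------------------------------------------------------------
# Patch-clamp K_ATP current
# ---------------------------------------------------------------------------

#: fully inhibiting ATP concentrations (mM) by preparation
FULLY_INHIBITING_MM = {"mouse": 10.0, "zebrafish": 5.0}


@dataclass
class PatchRecord:
    holding_potential_mv: float
    current_free_pa: float  # nucleotide-free solution
    current_inhibited_pa: float  # at fully inhibiting ATP
    inhibitor_mm: float
    species: str = "mouse"


def katp_current(record: PatchRecord) -> float:
    """K_ATP current: nucleotide-free current minus the current at a fully
    inhibiting ATP concentration. Raises when the applied concentration is
    below the declared fully-inhibiting level for the preparation."""
    required = FULLY_INHIBITING_MM.get(record.species)
    if required is not None and record.inhibitor_mm < required:
        raise ValueError(
            f"{record.inhibitor_mm} mM ATP below the fully inhibiting "
            f"{required} mM for {record.species}"
        )
    diff = record.current_free_pa - record.current_inhibited_pa
    if diff < 0:
        warnings.warn("inhibited current exceeds nucleotide-free current")
    return diff


# ---------------------------------------------------------------------------
# Relative expression (2^-ddCt / Pfaffl)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMeasurement:
    """Ct values for the target and reference gene in one sample pool."""

    sample: str
    ct_target: float
    ct_reference: float
    is_wildtype: bool = False

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")


def relative_expression(
    measurements: Sequence[ExpressionMeasurement],
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
) -> dict[str, float]:
    """Efficiency-corrected relative expression per sample pool, normalized
    to the mean of the wild-type pools (Pfaffl ratio
    ``E_t^dCt_t / E_ref^dCt_ref`` with dCt = mean WT Ct - sample Ct).
    With both efficiencies at 2 this is exactly 2^-ddCt."""
    for e in (efficiency_target, efficiency_reference):
        if not 1.0 < e <= 2.0:
            raise ValueError("amplification efficiencies must be in (1, 2]")
    wt = [m for m in measurements if m.is_wildtype]
    if not wt:
        raise ValueError("at least one wild-type pool required")
    mean_wt_t = float(np.mean([m.ct_target for m in wt]))
    mean_wt_r = float(np.mean([m.ct_reference for m in wt]))
    out = {}
    for m in measurements:
        dct_t = mean_wt_t - m.ct_target
        dct_r = mean_wt_r - m.ct_reference
        out[m.sample] = efficiency_target**dct_t / efficiency_reference**dct_r
    return out


# ---------------------------------------------------------------------------
# Group comparison plumbing
# ---------------------------------------------------------------------------

def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "mann_whitney",
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Two-sided group comparison (Mann-Whitney U or Welch t), optionally
    with a Bonferroni-corrected significance threshold alpha/n."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "t_two_tailed":
        res = stats.ttest_ind(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "alpha_corrected": bonferroni_threshold(alpha, n_comparisons),
    }


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance threshold alpha / n."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons
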