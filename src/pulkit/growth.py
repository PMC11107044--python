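"""Growth-curve phenotyping for anaerobic batch cultures monitored by OD600.

Cultures of polysaccharide-degrading rumen bacteria are followed at fixed
sampling intervals; once the optical density reaches a dilution threshold the
culture is diluted and immediately re-measured so that readings stay in the
spectrophotometer's linear range.  This module stitches such diluted curves
back together, locates the exponential phase, applies the two-point specific
growth-rate formula

    mu = (ln(A_max) - ln(A_min)) / (T_max - T_min)

to the minimum and maximum OD inside that phase, records the maximum
dilution-corrected OD, and classifies growth on a substrate as *poor*, *good*
or *excellent*.  It also predicts expected growth on a polysaccharide from
its monosaccharide composition as a weighted sum of the rates (or maximum
densities) measured on the pure monosaccharides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthCurve",
    "GrowthSummary",
    "CompositionWeights",
    "stitch_dilutions",
    "estimate_growth_rate",
    "max_od",
    "classify_growth",
    "expected_growth",
    "summarize_replicates",
]

#: OD readings below this are excluded from exponential-window search
#: (log-OD becomes numerically unstable near the blank).
DEFAULT_OD_FLOOR = 0.02

#: Minimum coefficient of determination for a log-linear window to count
#: as exponential phase.  Together with the 5-point minimum window this
#: keeps the maximal-slope selection from latching onto short runs of
#: measurement noise while still resolving fast growers (a culture at
#: 1.0/h spends only ~5 hourly samples in exponential phase).
DEFAULT_R2_MIN = 0.995
DEFAULT_MIN_POINTS = 5


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series with per-point dilution factors.

    ``measured_od`` holds the values as read off the instrument; the latent
    culture density is ``measured_od * dilution_factor``.  A factor of 1
    means the reading was taken on the undiluted culture.
    """

    time_h: np.ndarray
    measured_od: np.ndarray
    dilution_factor: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        od = np.asarray(self.measured_od, dtype=float)
        f = (
            np.ones_like(t)
            if self.dilution_factor is None
            else np.asarray(self.dilution_factor, dtype=float)
        )
        if not (t.shape == od.shape == f.shape) or t.ndim != 1:
            raise ValueError("time, OD and dilution factors must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(od)) or not np.all(np.isfinite(f)):
            raise ValueError("growth curve contains non-finite values")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "measured_od", od)
        object.__setattr__(self, "dilution_factor", f)

    def __len__(self) -> int:
        return self.time_h.size

    @property
    def od(self) -> np.ndarray:
        """Dilution-corrected (latent) OD."""
        return self.measured_od * self.dilution_factor


@dataclass(frozen=True)
class GrowthSummary:
    """Phenotype of one growth curve (or of averaged replicates)."""

    growth_rate: float
    max_od: float
    category: str | None
    window: tuple[float, float]
    a_min: float
    a_max: float
    rate_se: float = 0.0
    maxod_se: float = 0.0


@dataclass(frozen=True)
class CompositionWeights:
    """Monosaccharide composition of a polysaccharide.

    Weights may be supplied as fractions or percentages; they are
    renormalized to sum to 1 (manufacturer sheets mix both conventions).
    """

    polysaccharide: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.weights:
            raise ValueError("composition has no components")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("composition weights must be non-negative")
        total = float(sum(self.weights.values()))
        if total <= 0:
            raise ValueError("composition weights sum to zero")
        object.__setattr__(
            self, "weights", {k: v / total for k, v in self.weights.items()}
        )


def stitch_dilutions(curve: GrowthCurve) -> GrowthCurve:
    """Undo dilution events: multiply each reading by its dilution factor.

    Returns a curve on the latent OD scale with all factors reset to 1.
    Factors below 1 (a concentration step) are rejected.
    """
    if np.any(curve.dilution_factor < 1):
        raise ValueError("dilution factors must be >= 1")
    return GrowthCurve(
        curve.time_h.copy(),
        curve.measured_od * curve.dilution_factor,
        np.ones_like(curve.time_h),
    )


def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on t.  A constant window is treated
    as a perfect zero-slope fit (flat curves have rate 0, not undefined)."""
    tc = t - t.mean()
    yc = y - y.mean()
    ss_t = float(tc @ tc)
    ss_y = float(yc @ yc)
    if ss_y < 1e-24:
        return 0.0, 1.0
    slope = float(tc @ yc) / ss_t
    ss_res = ss_y - slope * float(tc @ yc)
    r2 = 1.0 - ss_res / ss_y
    return slope, r2


def estimate_growth_rate(
    curve: GrowthCurve,
    min_points: int = DEFAULT_MIN_POINTS,
    r2_min: float = DEFAULT_R2_MIN,
    od_floor: float = DEFAULT_OD_FLOOR,
) -> GrowthSummary:
    """Locate the exponential phase and apply the two-point rate formula.

    Every window of >= ``min_points`` consecutive usable points (OD above
    ``od_floor``) is fit by least squares on log-OD; windows with
    R^2 >= ``r2_min`` qualify as exponential phase and the one with maximal
    slope is selected (falling back to the best-R^2 window when none
    qualifies, as can happen on very noisy curves).  The reported rate is
    then the two-point formula evaluated at the window's minimum and
    maximum OD, which coincides with the fitted slope on clean data.  Ties
    among equal extreme values are broken toward the shortest span (last
    occurrence of the minimum, first of the maximum), so a window brushing
    the lag or plateau does not dilute the rate.

    The returned summary carries no category; combine with
    :func:`max_od` and :func:`classify_growth` (see
    :func:`summarize_replicates`).
    """
    stitched = stitch_dilutions(curve)
    od = stitched.od
    if np.any(od <= 0):
        raise ValueError("non-positive OD after stitching")
    usable = od >= od_floor
    t = stitched.time_h[usable]
    y = np.log(od[usable])
    n = t.size
    if n < min_points or min_points < 2:
        raise ValueError(
            f"need at least min_points={min_points} usable points, have {n}"
        )

    best = None  # (key, i, j)
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, r2 = _window_fit(t[i:j], y[i:j])
            key = (r2 >= r2_min, slope if r2 >= r2_min else r2)
            if best is None or key > best[0]:
                best = (key, i, j)
    _, i, j = best
    w_od = od[usable][i:j]
    w_t = t[i:j]
    a_min, a_max = float(w_od.min()), float(w_od.max())
    t_min = float(w_t[np.flatnonzero(w_od == a_min)[-1]])
    t_max = float(w_t[np.flatnonzero(w_od == a_max)[0]])
    if t_max == t_min:
        rate = 0.0
    else:
        rate = (math.log(a_max) - math.log(a_min)) / (t_max - t_min)
    return GrowthSummary(
        growth_rate=rate if rate > 0 else 0.0,
        max_od=float(od.max()),
        category=None,
        window=(min(t_min, t_max), max(t_min, t_max)),
        a_min=a_min,
        a_max=a_max,
    )


def max_od(curve: GrowthCurve) -> float:
    """Highest dilution-corrected OD measured over the whole curve."""
    if len(curve) == 0:
        raise ValueError("empty growth curve")
    return float(stitch_dilutions(curve).od.max())


def classify_growth(
    rate: float,
    maxod: float,
    rate_cutoff: float = 0.5,
    od_excellent: float = 3.0,
    od_poor: float = 1.5,
) -> str:
    """Three-category growth call from rate (1/h) and maximum density (OD).

    excellent: rate >= 0.5/h and density >= 3 OD; poor: rate < 0.5/h and
    density <= 1.5 OD; everything else good.  The rules are checked in that
    order and partition the plane.
    """
    if not (math.isfinite(rate) and math.isfinite(maxod)):
        raise ValueError("rate and maxOD must be finite")
    if rate < 0 or maxod < 0:
        raise ValueError("rate and maxOD must be non-negative")
    if rate >= rate_cutoff and maxod >= od_excellent:
        return "excellent"
    if rate < rate_cutoff and maxod <= od_poor:
        return "poor"
    return "good"


def expected_growth(
    weights: CompositionWeights,
    mono_table: dict[str, tuple[float, float]],
) -> tuple[float, float]:
    """Composition-weighted expected (rate, maxOD) on a polysaccharide.

    ``mono_table`` maps monosaccharide -> (growth rate, maxOD) measured on
    that sugar alone; the expectation is the weight-by-weight sum.
    """
    missing = [m for m in weights.weights if m not in mono_table]
    if missing:
        raise KeyError(f"no monosaccharide growth data for: {', '.join(sorted(missing))}")
    rate = sum(w * mono_table[m][0] for m, w in weights.weights.items())
    od = sum(w * mono_table[m][1] for m, w in weights.weights.items())
    return float(rate), float(od)


def summarize_replicates(
    curves: list[GrowthCurve],
    min_points: int = DEFAULT_MIN_POINTS,
    r2_min: float = DEFAULT_R2_MIN,
    od_floor: float = DEFAULT_OD_FLOOR,
    rate_cutoff: float = 0.5,
    od_excellent: float = 3.0,
    od_poor: float = 1.5,
) -> GrowthSummary:
    """Per-replicate rate and maxOD, averaged with standard errors.

    The category is assigned from the replicate means.
    """
    if not curves:
        raise ValueError("no replicate curves supplied")
    fits = [estimate_growth_rate(c, min_points, r2_min, od_floor) for c in curves]
    rates = np.array([f.growth_rate for f in fits])
    maxods = np.array([f.max_od for f in fits])
    k = len(fits)
    rate_se = float(rates.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    maxod_se = float(maxods.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    mean_rate = float(rates.mean())
    mean_maxod = float(maxods.mean())
    return GrowthSummary(
        growth_rate=mean_rate,
        max_od=mean_maxod,
        category=classify_growth(mean_rate, mean_maxod, rate_cutoff, od_excellent, od_poor),
        window=fits[0].window,
        a_min=float(np.mean([f.a_min for f in fits])),
        a_max=float(np.mean([f.a_max for f in fits])),
        rate_se=rate_se,
        maxod_se=maxod_se,
    )
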