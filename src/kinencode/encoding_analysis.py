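"""Lag-optimised correlation between firing rate and kinematic variables.

The procedure is a two-step, session-wide analysis carried out per (unit,
kinematic variable) pair on a common 30 ms grid:

1. **Cross-correlation.**  Pearson r is computed between the rate series and
   the kinematic series shifted by every integer lag in a symmetric window
   (default +/- 0.5 s); the lag maximising ``|r|`` wins.  Ties prefer the
   smallest ``|lag|``, then the negative (neural-activity-leading) lag.
2. **Shifted Pearson.**  The two signals are aligned at the winning lag and a
   plain Pearson correlation with its two-sided p value (t transform, n - 2
   degrees of freedom) is reported.

A unit's class is the variable with the largest ``|r|`` among those with
``p < alpha`` (default 0.05, per variable, no multiplicity correction —
deliberately matching the classical procedure); its sign is the sign of that
r.  Units significant for no variable are "uncorrelated".

Sign convention: ``lag_s > 0`` means the kinematic signal follows the neural
signal (neural activity leads movement).

The parametric p value ignores autocorrelation, which inflates significance
on long sessions.  An optional circular-shift permutation null
(``null="shuffle"``) gives honest inference; the default replicates the
classical analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kinematics import COMPONENT_NAMES, KinematicSet, component_parts, differentiate
from .unit_processing import RateSeries

DEFAULT_MIN_OVERLAP = 100


@dataclass
class LagWindow:
    """Symmetric lag search half-width in seconds."""

    max_lag_s: float = 0.5

    def __post_init__(self) -> None:
        if self.max_lag_s <= 0:
            raise ValueError("max_lag_s must be > 0")

    def bins(self, bin_width: float) -> int:
        return int(np.floor(self.max_lag_s / bin_width + 1e-9))


@dataclass
class VariableResult:
    """Best lag and shifted Pearson correlation for one kinematic variable."""

    variable: str
    best_lag_s: float
    best_lag_bins: int
    r: float
    p: float
    n: int
    undefined: bool = False


@dataclass
class EncodingResult:
    """Per-unit classification by the strongest significant kinematic variable."""

    unit_id: str
    per_variable: dict[str, VariableResult]
    class_variable: str  # one of the 8 components, or "uncorrelated"
    sign: str            # "positive" | "negative" | "none"
    class_r: float
    class_p: float
    class_lag_s: float
    alpha: float = 0.05

    @property
    def class_quantity(self) -> str:
        if self.class_variable == "uncorrelated":
            return "uncorrelated"
        return component_parts(self.class_variable)[0]

    @property
    def class_direction(self) -> str:
        if self.class_variable == "uncorrelated":
            return ""
        return component_parts(self.class_variable)[1]

    @property
    def class_lag_bins(self) -> float:
        if self.class_variable == "uncorrelated":
            return float("nan")
        return self.per_variable[self.class_variable].best_lag_bins


def _aligned(rate: np.ndarray, kin: np.ndarray, lag: int,
             rate_mask: np.ndarray | None, kin_mask: np.ndarray | None
             ) -> tuple[np.ndarray, np.ndarray]:
    """Overlap of ``rate[t]`` with ``kin[t + lag]``, valid bins only."""
    n = len(rate)
    if lag >= 0:
        a, b = rate[:n - lag], kin[lag:]
        am = rate_mask[:n - lag] if rate_mask is not None else None
        bm = kin_mask[lag:] if kin_mask is not None else None
    else:
        a, b = rate[-lag:], kin[:n + lag]
        am = rate_mask[-lag:] if rate_mask is not None else None
        bm = kin_mask[:n + lag] if kin_mask is not None else None
    valid = np.ones(len(a), dtype=bool)
    if am is not None:
        valid &= am
    if bm is not None:
        valid &= bm
    return a[valid], b[valid]


def _pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, or nan when either side has zero variance."""
    a = a - a.mean()
    b = b - b.mean()
    sa = np.sqrt(a @ a)
    sb = np.sqrt(b @ b)
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float((a @ b) / (sa * sb))


@dataclass
class LagScan:
    lag_bins: int
    lag_s: float
    r: float
    undefined: bool = False


def best_lag(rate: np.ndarray, kin: np.ndarray, bin_width: float,
             window: LagWindow | None = None,
             rate_mask: np.ndarray | None = None,
             kin_mask: np.ndarray | None = None,
             min_overlap: int = DEFAULT_MIN_OVERLAP) -> LagScan:
    """Find the integer lag maximising ``|r|`` between rate and kinematics.

    Masked bins are dropped pairwise at each lag (the overlap is recomputed,
    never imputed).  Lags with fewer than ``min_overlap`` jointly valid bins
    are skipped.  If the correlation is undefined at every admissible lag
    (zero variance), an ``undefined`` result is returned; it is treated as
    non-significant downstream.
    """
    window = window or LagWindow()
    rate = np.asarray(rate, dtype=float)
    kin = np.asarray(kin, dtype=float)
    if len(rate) != len(kin):
        raise ValueError("rate and kin must share the grid")
    L = window.bins(bin_width)
    best: LagScan | None = None
    # visit lags in tie-break preference order: |lag| ascending, negative first
    for lag in sorted(range(-L, L + 1), key=lambda l: (abs(l), l)):
        a, b = _aligned(rate, kin, lag, rate_mask, kin_mask)
        if len(a) < max(min_overlap, 3):
            continue
        r = _pearson_r(a, b)
        if np.isnan(r):
            continue
        if best is None or abs(r) > abs(best.r):
            best = LagScan(lag_bins=lag, lag_s=lag * bin_width, r=r)
    if best is None:
        return LagScan(lag_bins=0, lag_s=0.0, r=float("nan"), undefined=True)
    return best


def shifted_pearson(rate: np.ndarray, kin: np.ndarray, lag_bins: int,
                    rate_mask: np.ndarray | None = None,
                    kin_mask: np.ndarray | None = None
                    ) -> tuple[float, float, int]:
    """Pearson r and two-sided p at a fixed lag.

    p comes from the t transform of r with ``n - 2`` degrees of freedom,
    ``n`` being the number of jointly valid bins in the overlap.
    """
    a, b = _aligned(np.asarray(rate, float), np.asarray(kin, float),
                    int(lag_bins), rate_mask, kin_mask)
    n = len(a)
    if n < 3:
        raise ValueError("need >= 3 overlapping valid bins")
    r = _pearson_r(a, b)
    if np.isnan(r):
        return r, float("nan"), n
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), n


def circular_shift_null(rate: np.ndarray, kin: np.ndarray, bin_width: float,
                        window: LagWindow, n_shuffles: int,
                        rng: np.random.Generator,
                        rate_mask: np.ndarray | None = None,
                        kin_mask: np.ndarray | None = None,
                        min_overlap: int = DEFAULT_MIN_OVERLAP) -> np.ndarray:
    """Null distribution of the peak ``|r|`` under circular shifts of the rate.

    Circular shifting preserves the autocorrelation of both series while
    destroying their alignment, giving an honest null for session-long,
    autocorrelated signals.  Shift offsets are drawn uniformly outside the
    lag window.
    """
    n = len(rate)
    L = window.bins(bin_width)
    lo, hi = L + 1, n - L - 1
    if hi <= lo:
        raise ValueError("series too short for circular-shift null")
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = int(rng.integers(lo, hi))
        rr = np.roll(rate, shift)
        rm = np.roll(rate_mask, shift) if rate_mask is not None else None
        scan = best_lag(rr, kin, bin_width, window, rm, kin_mask, min_overlap)
        out[k] = np.nan if scan.undefined else abs(scan.r)
    return out


def classify_unit(rate: RateSeries, kinset: KinematicSet,
                  window: LagWindow | None = None, alpha: float = 0.05,
                  null: str = "pearson", n_shuffles: int = 1000,
                  rng: np.random.Generator | None = None,
                  min_overlap: int = DEFAULT_MIN_OVERLAP,
                  rate_mask: np.ndarray | None = None) -> EncodingResult:
    """Run the two-step analysis against all eight kinematic variables.

    The whole session (inter-trial intervals included) enters the
    correlation; the class label is the significant variable with the
    largest ``|r|``, or "uncorrelated" if none reaches ``p < alpha``.
    ``rate_mask`` optionally restricts the analysis to a subset of bins
    (e.g. concatenated peri-event windows).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if null not in ("pearson", "shuffle"):
        raise ValueError("null must be 'pearson' or 'shuffle'")
    window = window or LagWindow()
    if len(rate.rate) != len(kinset):
        raise ValueError("rate series and kinematic set must share the grid")
    per: dict[str, VariableResult] = {}
    for name in COMPONENT_NAMES:
        kin = kinset.components[name]
        kmask = kinset.component_mask(name)
        scan = best_lag(rate.rate, kin, rate.bin_width, window,
                        rate_mask, kmask, min_overlap)
        if scan.undefined:
            per[name] = VariableResult(name, float("nan"), 0, float("nan"),
                                       1.0, 0, undefined=True)
            continue
        r, p, n = shifted_pearson(rate.rate, kin, scan.lag_bins,
                                  rate_mask, kmask)
        if null == "shuffle":
            if rng is None:
                raise ValueError("shuffle null requires an rng")
            null_dist = circular_shift_null(rate.rate, kin, rate.bin_width,
                                            window, n_shuffles, rng,
                                            rate_mask, kmask, min_overlap)
            null_dist = null_dist[~np.isnan(null_dist)]
            p = (1.0 + np.count_nonzero(null_dist >= abs(r))) / (1.0 + len(null_dist))
        per[name] = VariableResult(name, scan.lag_s, scan.lag_bins, r, p, n)

    significant = [v for v in per.values() if not v.undefined and v.p < alpha]
    if not significant:
        return EncodingResult(rate.unit_id, per, "uncorrelated", "none",
                              float("nan"), float("nan"), float("nan"), alpha)
    top = max(significant, key=lambda v: abs(v.r))
    sign = "positive" if top.r > 0 else "negative"
    return EncodingResult(rate.unit_id, per, top.variable, sign,
                          top.r, top.p, top.best_lag_s, alpha)


OPPONENT_AXES = {
    "vel_horizontal": ("vel_left", "vel_right"),
    "vel_vertical": ("vel_up", "vel_down"),
    "acc_horizontal": ("acc_left", "acc_right"),
    "acc_vertical": ("acc_up", "acc_down"),
}


@dataclass
class OpponencySummary:
    """Opposite-direction correlation structure along one axis.

    ``r_opposite`` is evaluated at the *preferred* direction's best lag:
    because the two rectified halves of an axis are never jointly nonzero,
    their covariance at a common alignment is ``-E[a] E[b] < 0``, so a unit
    positively coupled to one direction must correlate negatively with the
    other direction there.  (At the opposite component's own best-|r| lag
    the sign can instead reflect bout sequencing, e.g. overshoot
    corrections.)  ``opponent`` is True when the two correlations have
    opposite signs; None when either is undefined (e.g. no movement ever
    occurred in one direction).
    """

    axis: str
    preferred: str
    r_preferred: float
    r_opposite: float
    opponent: bool | None


def opponency(result: EncodingResult,
              rate: "RateSeries | None" = None,
              kinset: KinematicSet | None = None) -> dict[str, OpponencySummary]:
    """Opponency summary per axis for one unit.

    With ``rate`` and ``kinset`` given, the opposite-direction r is
    recomputed at the preferred direction's best lag (the alignment at which
    the sign argument above holds); otherwise the stored per-variable
    records (each at its own best lag) are compared, which is weaker.
    """
    out: dict[str, OpponencySummary] = {}
    for axis, (a, b) in OPPONENT_AXES.items():
        ra, rb = result.per_variable[a], result.per_variable[b]
        if ra.undefined or rb.undefined:
            pref = b if ra.undefined and not rb.undefined else a
            out[axis] = OpponencySummary(axis, pref, float("nan"), float("nan"), None)
            continue
        if abs(ra.r) >= abs(rb.r):
            pref, opp = ra, rb
        else:
            pref, opp = rb, ra
        r_pref, r_opp = pref.r, opp.r
        if rate is not None and kinset is not None:
            kin = kinset.components[opp.variable]
            kmask = kinset.component_mask(opp.variable)
            r_opp, _, _ = shifted_pearson(rate.rate, kin, pref.best_lag_bins,
                                          None, kmask)
            if np.isnan(r_opp):
                out[axis] = OpponencySummary(axis, pref.variable, r_pref,
                                             float("nan"), None)
                continue
        out[axis] = OpponencySummary(axis, pref.variable, r_pref, r_opp,
                                     bool(r_pref * r_opp < 0))
    return out


@dataclass
class GabaDaResult:
    peak_r: float
    lag_s: float
    p: float
    undefined: bool = False


def gaba_da_derivative_test(gaba_rate: RateSeries, da_rate: RateSeries,
                            window: LagWindow | None = None,
                            min_overlap: int = DEFAULT_MIN_OVERLAP) -> GabaDaResult:
    """Correlate DA firing with the time derivative of GABA output firing.

    A pars reticulata GABA unit carrying position along an axis, paired with
    a DA unit carrying velocity along the same axis, should produce a
    mirror-image relationship: the derivative of the GABA rate correlates
    negatively with the DA rate (disinhibition).  Returns the peak r over
    the lag window and its lag.
    """
    window = window or LagWindow()
    if len(gaba_rate.rate) != len(da_rate.rate):
        raise ValueError("rate series must share the grid")
    deriv, _ = differentiate(gaba_rate.rate, gaba_rate.grid_t)
    # the two edge bins carry one-sided difference estimates with a
    # different truncation error; exclude them from the correlation
    dmask = np.ones(len(deriv), dtype=bool)
    dmask[0] = dmask[-1] = False
    scan = best_lag(da_rate.rate, deriv, da_rate.bin_width, window,
                    kin_mask=dmask, min_overlap=min_overlap)
    if scan.undefined:
        return GabaDaResult(float("nan"), float("nan"), float("nan"), True)
    r, p, _ = shifted_pearson(da_rate.rate, deriv, scan.lag_bins,
                              kin_mask=dmask)
    return GabaDaResult(peak_r=r, lag_s=scan.lag_s, p=p)
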