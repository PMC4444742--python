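"""Population-level tabulations and statistical tests.

Given per-unit encoding results, this module reproduces the standard
population summaries: a class count table (quantity x direction), the
positive/negative split, a hemisphere-by-preferred-direction lateralization
chi-square, a valence (appetitive vs aversive) proportion chi-square, a
one-way ANOVA of firing rate across classes, a Welch t-test of lag
magnitudes between positively and negatively correlated units, and a
genotype x stimulation-frequency two-way ANOVA for optogenetic sessions.

2x2 chi-square tests are Pearson's without the Yates continuity correction
(matching how such statistics are conventionally reported for these data);
pass ``yates=True`` for the corrected version.  The optogenetics ANOVA is a
fixed-effects two-way ANOVA on session-level summaries — a documented
simplification of a repeated-measures design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding_analysis import EncodingResult
from .kinematics import StimKinematics
from .session_io import UnitRecording

DIRECTIONS = ("up", "down", "left", "right")
QUANTITIES = ("velocity", "acceleration")


@dataclass
class ClassTable:
    """Counts of classified units by quantity, direction, sign and hemisphere."""

    counts: pd.DataFrame  # index QUANTITIES, columns DIRECTIONS
    n_uncorrelated: int
    n_positive: int
    n_negative: int
    # hemisphere -> quantity -> direction -> count
    hemisphere_counts: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def n_classified(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_dict(self) -> dict:
        return {
            "counts": {q: {d: int(self.counts.loc[q, d]) for d in DIRECTIONS}
                       for q in QUANTITIES},
            "n_uncorrelated": self.n_uncorrelated,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_classified": self.n_classified,
            "hemisphere_counts": {
                h: {q: {d: int(df.loc[q, d]) for d in DIRECTIONS} for q in QUANTITIES}
                for h, df in self.hemisphere_counts.items()},
        }


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(0, index=list(QUANTITIES), columns=list(DIRECTIONS))


def tabulate(results: list[EncodingResult],
             units: list[UnitRecording] | None = None) -> ClassTable:
    """Deterministic class counts from encoding results.

    ``units`` supplies hemisphere metadata; units with hemisphere "unknown"
    are tallied under "unknown" and excluded from lateralization.
    """
    hemi_of = {}
    if units is not None:
        hemi_of = {u.unit_id: u.hemisphere for u in units}
    counts = _empty_counts()
    hemis: dict[str, pd.DataFrame] = {}
    n_unc = n_pos = n_neg = 0
    for res in results:
        if res.class_variable == "uncorrelated":
            n_unc += 1
            continue
        q, d = res.class_quantity, res.class_direction
        counts.loc[q, d] += 1
        if res.sign == "positive":
            n_pos += 1
        elif res.sign == "negative":
            n_neg += 1
        h = hemi_of.get(res.unit_id, "unknown")
        if h not in hemis:
            hemis[h] = _empty_counts()
        hemis[h].loc[q, d] += 1
    return ClassTable(counts=counts, n_uncorrelated=n_unc,
                      n_positive=n_pos, n_negative=n_neg,
                      hemisphere_counts=hemis)


@dataclass
class ChiSquareResult:
    chi2: float
    p: float
    df: int = 1
    table: np.ndarray | None = None
    insufficient: bool = False


def chi_square_2x2(table, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    No continuity correction by default.  Raises on a zero marginal.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=yates)
    return ChiSquareResult(chi2=float(chi2), p=float(p), df=int(df), table=obs)


def lateralization_test(class_table: ClassTable,
                        yates: bool = False) -> dict[str, ChiSquareResult]:
    """Hemisphere x preferred-horizontal-direction chi-square per quantity.

    Tests whether left/right-preferring units are over-represented in the
    contralateral hemisphere, separately for velocity- and
    acceleration-classified units.  Quantities whose 2x2 table has a zero
    marginal are flagged ``insufficient`` rather than tested.
    """
    out: dict[str, ChiSquareResult] = {}
    for q in QUANTITIES:
        tbl = np.zeros((2, 2))
        for hi, hemi in enumerate(("left", "right")):
            df = class_table.hemisphere_counts.get(hemi)
            if df is not None:
                tbl[hi, 0] = df.loc[q, "left"]
                tbl[hi, 1] = df.loc[q, "right"]
        if np.any(tbl.sum(axis=0) == 0) or np.any(tbl.sum(axis=1) == 0):
            out[q] = ChiSquareResult(float("nan"), float("nan"), 1, tbl,
                                     insufficient=True)
        else:
            out[q] = chi_square_2x2(tbl, yates=yates)
    return out


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def class_rate_anova(results: list[EncodingResult], units: list[UnitRecording],
                     grouping: str = "direction") -> AnovaResult:
    """One-way ANOVA of mean firing rate across unit classes.

    ``grouping="direction"`` pools by preferred direction (4 groups);
    ``grouping="class_sign"`` crosses direction with correlation sign
    (up to 8 groups).  Uncorrelated units are excluded.
    """
    if grouping not in ("direction", "class_sign"):
        raise ValueError("grouping must be 'direction' or 'class_sign'")
    rate_of = {u.unit_id: u.mean_rate for u in units}
    groups: dict[str, list[float]] = {}
    for res in results:
        if res.class_variable == "uncorrelated" or res.unit_id not in rate_of:
            continue
        key = res.class_direction
        if grouping == "class_sign":
            key = f"{key}_{res.sign}"
        groups.setdefault(key, []).append(rate_of[res.unit_id])
    arrays = [np.asarray(v) for v in groups.values() if len(v) >= 2]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups with >= 2 units each")
    if all(a.var(ddof=1) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        n_total = sum(len(a) for a in arrays)
        return AnovaResult(0.0, len(arrays) - 1, n_total - len(arrays), 1.0)
    F, p = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    return AnovaResult(float(F), len(arrays) - 1, n_total - len(arrays), float(p))


@dataclass
class LagAsymmetryResult:
    mean_pos_s: float
    sem_pos_s: float
    n_pos: int
    mean_neg_s: float
    sem_neg_s: float
    n_neg: int
    t: float
    p: float
    flagged: bool = False  # degenerate (a sign class empty or zero variance)


def lag_asymmetry_test(results: list[EncodingResult]) -> LagAsymmetryResult:
    """Welch t-test of ``|class lag|`` between positive and negative units.

    Negatively correlated units (pauses preceding movement) typically show
    far longer lags than positively correlated (burst) units.
    """
    pos = np.array([abs(r.class_lag_s) for r in results if r.sign == "positive"])
    neg = np.array([abs(r.class_lag_s) for r in results if r.sign == "negative"])

    def _summ(a):
        if len(a) == 0:
            return float("nan"), float("nan")
        sem = float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan")
        return float(a.mean()), sem

    mp, sp = _summ(pos)
    mn, sn = _summ(neg)
    if len(pos) < 2 or len(neg) < 2:
        return LagAsymmetryResult(mp, sp, len(pos), mn, sn, len(neg),
                                  float("nan"), float("nan"), flagged=True)
    if pos.var(ddof=1) == 0 and neg.var(ddof=1) == 0:
        flagged = True
        t = 0.0 if mp == mn else float(np.sign(mp - mn) * np.inf)
        p = 1.0 if mp == mn else 0.0
        return LagAsymmetryResult(mp, sp, len(pos), mn, sn, len(neg), t, p, flagged)
    t, p = stats.ttest_ind(pos, neg, equal_var=False)
    return LagAsymmetryResult(mp, sp, len(pos), mn, sn, len(neg),
                              float(t), float(p))


@dataclass
class TwoWayAnovaResult:
    """Fixed-effects two-way ANOVA table for one response variable."""

    F_genotype: float
    p_genotype: float
    df_genotype: int
    F_frequency: float
    p_frequency: float
    df_frequency: int
    F_interaction: float
    p_interaction: float
    df_interaction: int
    df_resid: int


def _two_way_anova(df: pd.DataFrame, response: str) -> TwoWayAnovaResult:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    n_g = df["genotype"].nunique()
    n_f = df["frequency"].nunique()
    if df[response].var(ddof=0) == 0.0:
        # constant response: every effect is exactly zero
        return TwoWayAnovaResult(0.0, 1.0, n_g - 1, 0.0, 1.0, n_f - 1,
                                 0.0, 1.0, (n_g - 1) * (n_f - 1),
                                 len(df) - n_g * n_f)
    model = ols(f"{response} ~ C(genotype) * C(frequency)", data=df).fit()
    tbl = sm.stats.anova_lm(model, typ=2)

    def row(name):
        r = tbl.loc[name]
        return float(r["F"]), float(r["PR(>F)"]), int(r["df"])

    fg, pg, dg = row("C(genotype)")
    ff, pf, dfq = row("C(frequency)")
    fi, pi, di = row("C(genotype):C(frequency)")
    return TwoWayAnovaResult(fg, pg, dg, ff, pf, dfq, fi, pi, di,
                             int(tbl.loc["Residual", "df"]))


def stim_anova(summaries: pd.DataFrame) -> dict[str, TwoWayAnovaResult]:
    """Genotype x stimulation-frequency ANOVA on session-level movement metrics.

    ``summaries`` needs columns ``genotype``, ``frequency``, ``peak_speed``,
    ``distance``; one row per (session, frequency) cell.  Returns one ANOVA
    table per response.
    """
    for col in ("genotype", "frequency", "peak_speed", "distance"):
        if col not in summaries.columns:
            raise ValueError(f"missing column {col!r}")
    if summaries["genotype"].nunique() < 2 or summaries["frequency"].nunique() < 2:
        raise ValueError("each factor needs >= 2 levels")
    return {resp: _two_way_anova(summaries, resp)
            for resp in ("peak_speed", "distance")}


def stim_summaries(per_session: list[tuple[str, float, list[StimKinematics]]]
                   ) -> pd.DataFrame:
    """Collapse per-train metrics to session x frequency means.

    ``per_session`` items are ``(genotype, _session_id_or_idx, trains)``;
    train frequency is taken from each train's metadata.
    """
    rows = []
    for genotype, session, trains in per_session:
        by_freq: dict[float, list[StimKinematics]] = {}
        for tr in trains:
            by_freq.setdefault(tr.frequency_hz, []).append(tr)
        for freq, trs in by_freq.items():
            rows.append({
                "genotype": genotype, "session": session, "frequency": freq,
                "peak_speed": float(np.mean([t.peak_speed for t in trs])),
                "distance": float(np.mean([t.distance for t in trs])),
            })
    return pd.DataFrame(rows)


def population_report(results: list[EncodingResult],
                      units: list[UnitRecording]) -> dict:
    """Assemble the population.json payload: counts, proportions, tests."""
    table = tabulate(results, units)
    report: dict = {"class_table": table.to_dict()}
    n_total = len(results)
    n_cls = table.n_classified
    report["proportions"] = {
        "classified": n_cls / n_total if n_total else float("nan"),
        "positive_of_classified": table.n_positive / n_cls if n_cls else float("nan"),
        "negative_of_classified": table.n_negative / n_cls if n_cls else float("nan"),
    }
    try:
        lat = lateralization_test(table)
        report["lateralization"] = {
            q: ({"insufficient": True} if r.insufficient else
                {"chi2": r.chi2, "p": r.p, "df": r.df})
            for q, r in lat.items()}
    except ValueError as exc:
        report["lateralization"] = {"error": str(exc)}
    try:
        an = class_rate_anova(results, units)
        report["class_rate_anova"] = {"F": an.F, "df": [an.df_between, an.df_within],
                                      "p": an.p}
    except ValueError as exc:
        report["class_rate_anova"] = {"error": str(exc)}
    lag = lag_asymmetry_test(results)
    report["lag_asymmetry"] = {
        "mean_pos_s": lag.mean_pos_s, "sem_pos_s": lag.sem_pos_s, "n_pos": lag.n_pos,
        "mean_neg_s": lag.mean_neg_s, "sem_neg_s": lag.sem_neg_s, "n_neg": lag.n_neg,
        "t": lag.t, "p": lag.p, "flagged": lag.flagged,
    }
    return report
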