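"""Transition-day imputation from irregular ordinal phenology surveys.

Field crews score each tree on ordinal scales — budburst (bb) 1-5, crown
colouration (col) 1-8, leaf senescence (ls) 1-3 — every few days, so a tree
often passes a developmental stage *between* visits.  For each tree, trait
and year we:

1. reduce the survey to first-crossing points (the first day each attained
   stage was observed), dropping rare regressing scores with a warning;
2. fit a local-regression (LOESS) developmental curve through those points,
   degrading to the straight line when only two points exist;
3. solve curve(day) = stage threshold for each milestone stage, but only
   when the threshold is bracketed by observations on either side —
   extrapolation beyond the observed stage range is refused and the
   milestone is left undefined for that tree-year.

Milestone stages default to {bb2, bb4, co3, co8, ls3}; canopy duration is
CD = day(co3) - day(bb2).  A direct observation at a milestone always
overrides the curve estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: ordinal scale (min, max) per trait
SCALES: dict[str, tuple[int, int]] = {"bb": (1, 5), "col": (1, 8), "ls": (1, 3)}

#: canonical milestone labels -> (trait, ordinal threshold)
DEFAULT_STAGES: dict[str, tuple[str, int]] = {
    "bb2": ("bb", 2),
    "bb4": ("bb", 4),
    "co3": ("col", 3),
    "co8": ("col", 8),
    "ls3": ("ls", 3),
}

DEFAULT_SPAN = 0.75
MIN_POINTS = 2
_BISECT_TOL = 0.01  # days


class TransitionError(ValueError):
    pass


@dataclass
class DevelopmentalCurve:
    """Continuous stage-vs-day curve for one tree, trait and year.

    The LOESS fit is evaluated at the observed days and carried between
    them by a shape-preserving (PCHIP) interpolant, which keeps the curve
    free of overshoot between the short series' points.  Defined only on
    [days[0], days[-1]]; evaluation off-support raises.
    """

    days: np.ndarray
    stages: np.ndarray
    span: float = DEFAULT_SPAN

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.stages = np.asarray(self.stages, dtype=float)
        if len(self.days) < MIN_POINTS:
            raise TransitionError("need at least 2 first-crossing points to fit a curve")
        if len(self.days) == 2:
            # LOESS is undefined on two points: the line through them
            # preserves the bounded-interpolation contract
            self._interp = None
        else:
            fitted = lowess(
                self.stages, self.days, frac=self.span, it=0, return_sorted=False
            )
            self._interp = PchipInterpolator(self.days, fitted, extrapolate=False)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.days[0]), float(self.days[-1])

    def __call__(self, query_days) -> np.ndarray:
        q = np.atleast_1d(np.asarray(query_days, dtype=float))
        lo, hi = self.support
        if (q < lo - 1e-9).any() or (q > hi + 1e-9).any():
            raise TransitionError("curve evaluated outside its support")
        if self._interp is None:
            return np.interp(q, self.days, self.stages)
        return self._interp(np.clip(q, lo, hi))


def first_crossings(days, stages) -> tuple[np.ndarray, np.ndarray]:
    """Keep, for each attained stage, the first day it was observed.

    The output is strictly increasing in both day and stage.  Regressing
    scores (a later visit scoring below an earlier one) are biologically
    impossible within a season and are dropped with a warning.
    """
    days = np.asarray(days, dtype=float)
    stages = np.asarray(stages, dtype=float)
    if len(days) == 0:
        raise TransitionError("empty stage series")
    order = np.argsort(days, kind="stable")
    days, stages = days[order], stages[order]
    keep_d, keep_s = [days[0]], [stages[0]]
    for d, s in zip(days[1:], stages[1:]):
        if s > keep_s[-1]:
            keep_d.append(d)
            keep_s.append(s)
        elif s < keep_s[-1]:
            logger.warning(
                "regressing ordinal score (day %.0f stage %g after stage %g) dropped",
                d, s, keep_s[-1],
            )
    return np.array(keep_d), np.array(keep_s)


def fit_curve(days, stages, span: float = DEFAULT_SPAN) -> DevelopmentalCurve:
    """LOESS developmental curve through first-crossing points.

    With exactly two points LOESS is undefined and the curve degrades to the
    line through them, which preserves the bounded-interpolation contract.
    """
    if not 0 < span <= 1:
        raise TransitionError(f"span must be in (0, 1], got {span}")
    return DevelopmentalCurve(np.asarray(days, float), np.asarray(stages, float), span)


def _bracket(days, scores, threshold):
    """Tightest raw-visit pair around a threshold crossing.

    Returns (d_lo, s_lo, d_hi, s_hi) where d_lo is the *last* visit scored
    below the threshold and d_hi the first visit at/above it, or None when
    the crossing is not bounded by observations on either side.
    """
    days = np.asarray(days, dtype=float)
    scores = np.asarray(scores, dtype=float)
    above = np.nonzero(scores >= threshold)[0]
    if not above.size:
        return None
    hi = int(above[0])
    below = np.nonzero((scores < threshold) & (days < days[hi]))[0]
    if not below.size:
        return None
    lo = int(below[-1])
    return float(days[lo]), float(scores[lo]), float(days[hi]), float(scores[hi])


def transition_day(
    curve: DevelopmentalCurve,
    threshold: float,
    bracket: tuple[float, float, float, float] | None = None,
) -> tuple[float | None, str]:
    """Day the developmental curve first reaches `threshold`.

    Returns (day, source) with source in {"observed", "imputed"} or
    (None, "undefined").  A direct observation at the threshold takes
    precedence.  Otherwise the crossing is solved by bisection to 0.01-day
    tolerance inside the bracketing pair of observations — by default the
    neighbouring first-crossing points, or the (tighter) raw-visit pair in
    `bracket` = (d_lo, s_lo, d_hi, s_hi) when the caller has the full
    survey.  When the fitted curve does not cross inside the bracket (a
    multi-stage jump between visits leaves LOESS uninformed there), the
    chord between the bracketing observations is used instead.  The
    estimate is always strictly inside the bracket; thresholds outside the
    observed stage range are undefined (no extrapolation).
    """
    d, s = curve.days, curve.stages
    hit = np.nonzero(s == threshold)[0]
    if hit.size:
        return float(d[hit[0]]), "observed"
    if threshold < s[0] or threshold > s[-1]:
        return None, "undefined"
    if bracket is None:
        hi = int(np.searchsorted(s, threshold))  # first index with stage >= threshold
        bracket = (float(d[hi - 1]), float(s[hi - 1]), float(d[hi]), float(s[hi]))
    d_lo, s_lo, d_hi, s_hi = bracket
    if d_hi - d_lo <= 2 * _BISECT_TOL:
        return 0.5 * (d_lo + d_hi), "imputed"
    lo_sup, hi_sup = curve.support
    a, b = max(d_lo, lo_sup), min(d_hi, hi_sup)
    crossed = False
    if a < b:
        fa = float(curve(a)[0]) - threshold
        fb = float(curve(b)[0]) - threshold
        crossed = fa < 0 <= fb
    if crossed:
        while b - a > _BISECT_TOL:
            m = 0.5 * (a + b)
            if float(curve(m)[0]) - threshold < 0:
                a = m
            else:
                b = m
        day = 0.5 * (a + b)
    else:
        day = d_lo + (d_hi - d_lo) * (threshold - s_lo) / (s_hi - s_lo)
    # keep the estimate strictly inside the bracketing observations
    day = min(max(day, d_lo + _BISECT_TOL), d_hi - _BISECT_TOL)
    return float(day), "imputed"


def _series_groups(survey: pd.DataFrame):
    required = {"tree_id", "genotype_id", "year", "doy", "trait", "score"}
    missing = required - set(survey.columns)
    if missing:
        raise TransitionError(f"survey table missing columns {sorted(missing)}")
    return survey.groupby(["tree_id", "year", "trait"], sort=True)


def build_transition_table(
    survey: pd.DataFrame,
    stages: dict[str, tuple[str, int]] | None = None,
    span: float = DEFAULT_SPAN,
) -> pd.DataFrame:
    """One row per tree x year x milestone stage.

    Columns: tree_id, genotype_id, year, stage, doy, source.  `doy` is NaN
    and source "undefined" where the milestone was not bracketed by
    observations (or the tree-trait-year had < 2 usable points).
    """
    stages = stages or DEFAULT_STAGES
    by_trait: dict[str, list[tuple[str, int]]] = {}
    for label, (trait, thr) in stages.items():
        by_trait.setdefault(trait, []).append((label, thr))
    genotype_of = (
        survey.drop_duplicates("tree_id").set_index("tree_id")["genotype_id"].to_dict()
    )
    trees = sorted(survey["tree_id"].unique())
    years = sorted(survey["year"].unique())
    results: dict[tuple, tuple[float, str]] = {}
    for (tree, year, trait), grp in _series_groups(survey):
        labels = by_trait.get(trait)
        if not labels:
            continue
        raw_d = grp["doy"].to_numpy(dtype=float)
        raw_s = grp["score"].to_numpy(dtype=float)
        d, s = first_crossings(raw_d, raw_s)
        if len(d) < MIN_POINTS:
            continue
        curve = fit_curve(d, s, span)
        for label, thr in labels:
            day, source = transition_day(curve, thr, bracket=_bracket(raw_d, raw_s, thr))
            if day is not None:
                results[(tree, year, label)] = (day, source)
    rows = []
    for tree in trees:
        for year in years:
            for label in stages:
                day, source = results.get((tree, year, label), (np.nan, "undefined"))
                rows.append((tree, genotype_of.get(tree), year, label, day, source))
    return pd.DataFrame(
        rows, columns=["tree_id", "genotype_id", "year", "stage", "doy", "source"]
    )


def canopy_duration(table: pd.DataFrame) -> pd.DataFrame:
    """CD = day(co3) - day(bb2) per tree-year; rows with either endpoint
    undefined are omitted."""
    wide = table.pivot(
        index=["tree_id", "genotype_id", "year"], columns="stage", values="doy"
    )
    for col in ("bb2", "co3"):
        if col not in wide.columns:
            raise TransitionError(f"transition table lacks stage {col!r}")
    cd = (wide["co3"] - wide["bb2"]).dropna()
    out = cd.reset_index()
    out.columns = ["tree_id", "genotype_id", "year", "cd_days"]
    return out


def validate_imputation(imputed, observed) -> float:
    """Pearson correlation between imputed and held-out observed days."""
    imputed = np.asarray(imputed, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if imputed.shape != observed.shape or imputed.ndim != 1:
        raise TransitionError("imputed/observed must be equal-length 1-d arrays")
    if len(imputed) < 3:
        raise TransitionError("need at least 3 paired values")
    return float(stats.pearsonr(imputed, observed).statistic)


def holdout_validation(
    survey: pd.DataFrame,
    stages: dict[str, tuple[str, int]] | None = None,
    span: float = DEFAULT_SPAN,
) -> pd.DataFrame:
    """Leave-one-out check of the imputation against direct observations.

    For every tree-year milestone whose crossing was directly observed
    (some visit scored the tree at exactly the threshold stage), drop every
    visit at that stage, refit the developmental curve on the remaining
    observations and re-impute the milestone day.  Returns one row per
    recoverable holdout: tree_id, year, stage, observed_doy (the first day
    the stage was actually seen), imputed_doy.  Correlate the two columns
    (pooled or per-stage) with `validate_imputation`.
    """
    stages = stages or DEFAULT_STAGES
    by_trait: dict[str, list[tuple[str, int]]] = {}
    for label, (trait, thr) in stages.items():
        by_trait.setdefault(trait, []).append((label, thr))
    rows = []
    for (tree, year, trait), grp in _series_groups(survey):
        labels = by_trait.get(trait)
        if not labels:
            continue
        raw_d = grp["doy"].to_numpy(dtype=float)
        raw_s = grp["score"].to_numpy(dtype=float)
        for label, thr in labels:
            hit = np.nonzero(raw_s == thr)[0]
            if not hit.size:
                continue
            observed_doy = float(raw_d[hit[0]])
            keep = raw_s != thr
            d2, s2 = first_crossings(raw_d[keep], raw_s[keep])
            if len(d2) < MIN_POINTS or thr < s2[0] or thr > s2[-1]:
                continue
            day, source = transition_day(
                fit_curve(d2, s2, span), thr, bracket=_bracket(raw_d[keep], raw_s[keep], thr)
            )
            if day is None or source != "imputed":
                continue
            rows.append((tree, year, label, observed_doy, day))
    return pd.DataFrame(
        rows, columns=["tree_id", "year", "stage", "observed_doy", "imputed_doy"]
    )


def read_survey_csv(path) -> pd.DataFrame:
    """Read the long-format survey CSV `tree_id,genotype_id,year,doy,trait,score`."""
    df = pd.read_csv(
        path,
        dtype={"tree_id": str, "genotype_id": str, "trait": str},
    )
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        if row.trait not in SCALES:
            raise TransitionError(f"line {i}: unknown trait {row.trait!r}")
        lo, hi = SCALES[row.trait]
        if not lo <= row.score <= hi:
            raise TransitionError(
                f"line {i}: score {row.score} outside {row.trait} scale [{lo}, {hi}]"
            )
    if df.empty:
        raise TransitionError("empty survey file")
    return df
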