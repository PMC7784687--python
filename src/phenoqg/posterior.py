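"""Genetic summaries and chain diagnostics from retained draws.

All derived quantities are computed per draw and only then summarized:
h2 = G[t,t] / (G[t,t] + R[t,t]) and r = G[i,j] / sqrt(G[i,i] G[j,j]) are
nonlinear in (G, R), so summarizing first and deriving after gives biased
answers.  Because every retained G is positive definite, per-draw genetic
correlations always lie in [-1, 1] — printed interval bounds outside that
range (as sometimes seen in the literature) cannot arise on this path and
are not reproduced.

Point estimates are posterior medians (with means alongside); intervals are
central quantile or highest-posterior-density (HPD), default HPD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .animal_model import PosteriorDraws


class SummaryError(ValueError):
    pass


@dataclass
class GeneticSummary:
    parameter: str
    median: float
    mean: float
    lower: float
    upper: float
    level: float
    kind: str
    ess: float
    lag1: float

    @property
    def excludes_zero(self) -> bool:
        """Report-flagging rule: the credible interval does not overlap zero."""
        return self.lower > 0 or self.upper < 0


def credible_interval(series, level: float = 0.95, kind: str = "hpd") -> tuple[float, float]:
    """Central quantile or highest-posterior-density interval.

    The HPD interval is the shortest window of sorted draws containing
    `level` of them; for skewed posteriors it is strictly narrower than the
    central quantile interval.
    """
    if not 0 < level < 1:
        raise SummaryError(f"level must be in (0, 1), got {level}")
    x = np.sort(np.asarray(series, dtype=float))
    n = len(x)
    if kind == "quantile":
        alpha = (1 - level) / 2
        return float(np.quantile(x, alpha)), float(np.quantile(x, 1 - alpha))
    if kind == "hpd":
        k = max(1, int(np.ceil(level * n)))
        if k >= n:
            return float(x[0]), float(x[-1])
        widths = x[k:] - x[: n - k]
        i = int(np.argmin(widths))
        return float(x[i]), float(x[i + k])
    raise SummaryError(f"unknown interval kind {kind!r}")


def autocorrelation(series, lag: int = 1) -> float:
    """Sample autocorrelation at the given lag of the retained-draw series."""
    x = np.asarray(series, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[:-lag] @ x[lag:]) / denom


def effective_sample_size(series) -> float:
    """ESS = n / (1 + 2 * sum of autocorrelations over positive lags).

    The sum is truncated at the first non-positive autocorrelation
    (initial-positive-sequence rule), which keeps the estimate stable for
    well-thinned chains whose true autocorrelations are near zero.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    total = 0.0
    for lag in range(1, n // 2):
        rho = autocorrelation(x, lag)
        if rho <= 0:
            break
        total += rho
    return n / (1 + 2 * total)


def chain_diagnostics(series) -> dict[str, float]:
    series = np.asarray(series, dtype=float)
    if len(series) < 100:
        raise SummaryError("need at least 100 retained draws for diagnostics")
    return {
        "lag1": autocorrelation(series, 1),
        "ess": effective_sample_size(series),
    }


def summarize_series(
    series, parameter: str, level: float = 0.95, kind: str = "hpd"
) -> GeneticSummary:
    series = np.asarray(series, dtype=float)
    if len(series) < 100:
        raise SummaryError("need at least 100 draws to summarize")
    lower, upper = credible_interval(series, level, kind)
    return GeneticSummary(
        parameter=parameter,
        median=float(np.median(series)),
        mean=float(series.mean()),
        lower=lower,
        upper=upper,
        level=level,
        kind=kind,
        ess=effective_sample_size(series),
        lag1=autocorrelation(series, 1),
    )


def heritability(
    draws: PosteriorDraws, trait: str, level: float = 0.95, kind: str = "hpd"
) -> tuple[np.ndarray, GeneticSummary]:
    """Per-draw narrow-sense heritability h2 = Va / (Va + Ve) for one trait.

    Defined at the genotype level: Va is the additive (genotype) variance
    and Ve the residual, which includes among-ramet variation.
    """
    i = draws.trait_index(trait)
    va = draws.G[:, i, i]
    ve = draws.R[:, i, i]
    series = va / (va + ve)
    return series, summarize_series(series, f"h2[{trait}]", level, kind)


def genetic_correlation(
    draws: PosteriorDraws,
    trait_i: str,
    trait_j: str,
    level: float = 0.95,
    kind: str = "hpd",
) -> tuple[np.ndarray, GeneticSummary]:
    """Per-draw genetic correlation: covariance over the geometric mean of
    the variances."""
    i = draws.trait_index(trait_i)
    j = draws.trait_index(trait_j)
    series = draws.G[:, i, j] / np.sqrt(draws.G[:, i, i] * draws.G[:, j, j])
    return series, summarize_series(series, f"r[{trait_i},{trait_j}]", level, kind)


def summarize(
    draws: PosteriorDraws, level: float = 0.95, kind: str = "hpd"
) -> pd.DataFrame:
    """All heritabilities and pairwise genetic correlations as a flat table.

    Columns: parameter, median, mean, lower, upper, kind, ess, lag1,
    excludes_zero.
    """
    out = []
    for trait in draws.traits:
        _, s = heritability(draws, trait, level, kind)
        out.append(s)
    for i, ti in enumerate(draws.traits):
        for tj in draws.traits[i + 1 :]:
            _, s = genetic_correlation(draws, ti, tj, level, kind)
            out.append(s)
    return pd.DataFrame(
        [
            (
                s.parameter, s.median, s.mean, s.lower, s.upper,
                s.kind, s.ess, s.lag1, s.excludes_zero,
            )
            for s in out
        ],
        columns=[
            "parameter", "median", "mean", "lower", "upper",
            "kind", "ess", "lag1", "excludes_zero",
        ],
    )


def correlation_table(
    draws: PosteriorDraws, level: float = 0.95, kind: str = "hpd"
) -> pd.DataFrame:
    """Lower-triangle genetic-correlation matrix formatted like a results
    table: `median (lower,upper)`, with `*` marking intervals that exclude
    zero."""
    t = len(draws.traits)
    cells = [["" for _ in range(t - 1)] for _ in range(t - 1)]
    for i in range(1, t):
        for j in range(i):
            _, s = genetic_correlation(draws, draws.traits[j], draws.traits[i], level, kind)
            flag = "*" if s.excludes_zero else ""
            cells[i - 1][j] = f"{s.median:.3f} ({s.lower:.3f},{s.upper:.3f}){flag}"
    return pd.DataFrame(
        cells, index=draws.traits[1:], columns=draws.traits[:-1]
    )
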