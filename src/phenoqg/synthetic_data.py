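"""Synthetic clonal-trial generator.

Emulates the statistical design of the phenology study end to end so that
every pipeline stage (imputation, animal model, posterior summaries) can be
tested without field data:

* a 9-female x 10-male crossing design producing 34 full-sib families and
  120 genotypes, clonally replicated into 564 trees (1-20 ramets per
  genotype, median 6);
* multivariate breeding values drawn from the A (x) G structure of the
  pedigree animal model, with generative G assembled from the study's
  printed genetic-correlation and heritability estimates;
* latent transition days for the milestone stages {bb2, bb4, co3, co8, ls3}
  in two years, with canopy duration CD = co3 - bb2 by construction and DBH
  on its own scale;
* ordinal surveys every 2-5 days observing the latent process piecewise-
  constantly (a stage is scored once its true day has passed).

Cross-year genetic structure: each trait has a target cross-year genetic
correlation r_t; the 12x12 (6 free traits x 2 years) genetic covariance is
assembled as [[G, C], [C, G]] with C = D G D, D = diag(sqrt(r_t)).  When the
r_t differ between traits this matrix can be slightly indefinite and is
projected to the nearest PD matrix, which perturbs the realized parameters
by a few hundredths; the *realized* (post-projection) parameters, including
the induced CD row, are what `truth` reports and what recovery experiments
should be scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import nearest_pd, safe_cholesky
from .pedigree import (
    CloneMap,
    Pedigree,
    RelationshipMatrix,
    additive_relationship,
    build_pedigree,
    clone_incidence,
    write_clone_map_csv,
    write_pedigree_csv,
)

#: the seven analysis traits, in canonical order
TRAITS7 = ["bb2", "bb4", "co3", "co8", "ls3", "cd", "dbh"]
#: the six freely simulated traits (cd is derived as co3 - bb2)
FREE_TRAITS = ["bb2", "bb4", "co3", "co8", "ls3", "dbh"]

#: printed genetic correlations among the free traits (lower-triangle pairs)
TABLE1_CORRELATIONS: dict[tuple[str, str], float] = {
    ("bb2", "bb4"): 0.768,
    ("bb2", "co3"): 0.120,
    ("bb2", "co8"): 0.059,
    ("bb2", "ls3"): 0.211,
    ("bb2", "dbh"): -0.317,
    ("bb4", "co3"): 0.219,
    ("bb4", "co8"): 0.134,
    ("bb4", "ls3"): 0.255,
    ("bb4", "dbh"): -0.418,
    ("co3", "co8"): 0.868,
    ("co3", "ls3"): 0.808,
    ("co3", "dbh"): 0.254,
    ("co8", "ls3"): 0.800,
    ("co8", "dbh"): 0.394,
    ("ls3", "dbh"): 0.334,
}


class GeneratorError(ValueError):
    pass


def _default_means():
    # plausible day-of-year anchors (the analysis only uses differences);
    # dbh in cm
    return {"bb2": 115.0, "bb4": 130.0, "co3": 255.0, "co8": 280.0, "ls3": 295.0, "dbh": 25.0}


def _default_shifts():
    # second-year shifts, days: everything earlier, 3 d (budburst, leaf
    # shed) to ~10 d (full yellow)
    return {"bb2": -3.0, "bb4": -7.0, "co3": -6.0, "co8": -10.0, "ls3": -3.0, "dbh": 0.0}


def _default_h2():
    return {"bb2": 0.60, "bb4": 0.55, "co3": 0.50, "co8": 0.45, "ls3": 0.62, "dbh": 0.76}


def _default_phenotypic_sd():
    # day-scale SDs chosen so that bb2 and co3 share the same *genetic*
    # variance (20.25 d^2), which makes the induced CD = co3 - bb2 row
    # reproduce the printed CD correlations; dbh in cm
    return {"bb2": 5.8095, "bb4": 6.0, "co3": 6.3640, "co8": 6.0, "ls3": 6.0, "dbh": 5.0}


def _default_cross_year_r():
    # the trial default keeps genotype effects constant across years, which
    # is exactly the assumption of the stacked multi-trait model with a
    # fixed year effect; cross-year experiments (the bivariate model) set
    # per-trait values < 1 explicitly
    return {t: 1.0 for t in FREE_TRAITS}


@dataclass
class GeneratorConfig:
    n_females: int = 9
    n_males: int = 10
    n_families: int = 34
    n_genotypes: int = 120
    n_trees: int = 564
    ramet_min: int = 1
    ramet_max: int = 20
    ramet_median: int = 6
    years: tuple[int, int] = (2017, 2018)
    gap_min: int = 2
    gap_max: int = 5
    spring_window: tuple[int, int] = (92, 168)
    autumn_window: tuple[int, int] = (222, 326)
    trait_means: dict[str, float] = field(default_factory=_default_means)
    year_shifts: dict[str, float] = field(default_factory=_default_shifts)
    heritability: dict[str, float] = field(default_factory=_default_h2)
    phenotypic_sd: dict[str, float] = field(default_factory=_default_phenotypic_sd)
    cross_year_r: dict[str, float] = field(default_factory=_default_cross_year_r)
    ordering_margin: float = 1.0
    max_rejections: int = 1000
    seed: int = 20170908

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        """Copy with scalar fields and/or per-trait dict entries replaced."""
        out = replace(self)
        for key, value in kwargs.items():
            current = getattr(out, key)
            if isinstance(current, dict) and isinstance(value, dict):
                setattr(out, key, {**current, **value})
            else:
                setattr(out, key, value)
        return out

    def genetic_covariance(self) -> tuple[np.ndarray, np.ndarray]:
        """Day-scale (G, R) for the six free traits; R is diagonal."""
        vg = np.array(
            [self.heritability[t] * self.phenotypic_sd[t] ** 2 for t in FREE_TRAITS]
        )
        ve = np.array(
            [(1 - self.heritability[t]) * self.phenotypic_sd[t] ** 2 for t in FREE_TRAITS]
        )
        corr = np.eye(len(FREE_TRAITS))
        index = {t: i for i, t in enumerate(FREE_TRAITS)}
        for (a, b), r in TABLE1_CORRELATIONS.items():
            corr[index[a], index[b]] = corr[index[b], index[a]] = r
        sd = np.sqrt(vg)
        return nearest_pd(corr * np.outer(sd, sd)), np.diag(ve)

    def cross_year_genetic_covariance(self) -> np.ndarray:
        """Realized 12x12 genetic covariance (free traits x years)."""
        G, _ = self.genetic_covariance()
        r = np.array([self.cross_year_r[t] for t in FREE_TRAITS])
        d = np.sqrt(np.clip(r, 0.0, 1.0))
        C = G * np.outer(d, d)
        return nearest_pd(np.block([[G, C], [C, G]]))


@dataclass
class LatentTrial:
    """Everything the generator knows: pedigree, layout and latent truth."""

    pedigree: Pedigree
    clone_map: CloneMap
    tree_table: pd.DataFrame  # tree_id, genotype_id
    relationship: RelationshipMatrix  # genotype-level A
    true_days: pd.DataFrame  # tree_id, genotype_id, year, all stage days, cd
    dbh: pd.DataFrame  # tree_id, genotype_id, dbh_cm
    breeding_values: np.ndarray  # q x 12 (free traits x years)
    truth: dict


@dataclass
class SyntheticDataset:
    trial: LatentTrial
    survey: pd.DataFrame
    config: GeneratorConfig

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree_csv(self.trial.pedigree, outdir / "pedigree.csv")
        write_clone_map_csv(self.trial.clone_map, outdir / "clone_map.csv")
        self.survey.to_csv(outdir / "survey.csv", index=False)
        self.trial.dbh.to_csv(outdir / "dbh.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.trial.truth, fh, indent=1, sort_keys=True)
        return [
            outdir / name
            for name in ("pedigree.csv", "clone_map.csv", "survey.csv", "dbh.csv", "truth.json")
        ]


def _ramet_counts(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Ramet counts with exact sum, exact median, and range respected.

    A deterministic multiset satisfying all four constraints exactly is
    built, then assigned to genotypes by seeded permutation.  (Random draws
    would only meet the trial's summary statistics in expectation.)
    """
    n, total = config.n_genotypes, config.n_trees
    med, lo, hi = config.ramet_median, config.ramet_min, config.ramet_max
    if not lo <= med <= hi or total < n * lo or total > n * hi:
        raise GeneratorError("infeasible ramet configuration")
    counts = np.full(n, med, dtype=int)
    # with the middle order statistic(s) pinned at the median, the first
    # n_low entries may drop below it and the last n_high may rise above
    n_mid = 2 if n % 2 == 0 else 1
    n_low = (n - n_mid) // 2
    n_high = n - n_low - n_mid
    deficit = int(counts.sum()) - total  # >0: shrink low side; <0: grow high side
    if deficit > n_low * (med - lo) or -deficit > n_high * (hi - med):
        raise GeneratorError("cannot satisfy ramet sum within range and median")
    if deficit >= 0:
        # give the tail some spread up to the maximum, then shrink the low
        # side greedily toward the minimum to restore the total
        spread = min(n_low * (med - lo) - deficit, n_high * (hi - med), 3 * (hi - med))
        bumps: list[int] = []
        b = hi - med
        while spread > 0 and b >= 1 and len(bumps) < n_high:
            take = min(b, spread)
            bumps.append(take)
            spread -= take
            b = max(1, int(b * 0.65)) if b > 1 else 0
        for i, bump in enumerate(bumps):
            counts[n - 1 - i] += bump
        deficit += sum(bumps)
        i = 0
        while deficit > 0 and i < n_low:
            take = min(med - lo, deficit)
            counts[i] -= take
            deficit -= take
            i += 1
    else:
        i = 0
        while deficit < 0:
            j = n - 1 - (i % n_high)
            if counts[j] < hi:
                counts[j] += 1
                deficit += 1
            i += 1
    counts = np.sort(counts)
    if counts.sum() != total or np.median(counts) != med or counts.min() < lo or counts.max() > hi:
        raise GeneratorError("ramet count construction failed")
    return counts[rng.permutation(n)]


def simulate_crossing_design(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[Pedigree, pd.DataFrame]:
    """Founders, families, genotypes and the clonal field layout.

    Returns the sorted pedigree (founders + offspring genotypes) and the
    tree table (`tree_id, genotype_id`), deterministic under the rng state.
    """
    n_pairs = config.n_females * config.n_males
    if config.n_families > n_pairs:
        raise GeneratorError(
            f"{config.n_families} families infeasible from "
            f"{config.n_females}x{config.n_males} parents"
        )
    dams = [f"F{i+1:02d}" for i in range(config.n_females)]
    sires = [f"M{i+1:02d}" for i in range(config.n_males)]
    all_pairs = [(s, d) for s in sires for d in dams]
    chosen = [all_pairs[i] for i in rng.choice(n_pairs, size=config.n_families, replace=False)]
    # near-uniform allocation of genotypes to families
    base, extra = divmod(config.n_genotypes, config.n_families)
    fam_sizes = np.full(config.n_families, base)
    fam_sizes[rng.choice(config.n_families, size=extra, replace=False)] += 1
    records = [(g, None, None) for g in dams + sires]
    g_idx = 0
    for (sire, dam), size in zip(chosen, fam_sizes):
        for _ in range(size):
            g_idx += 1
            records.append((f"G{g_idx:03d}", sire, dam))
    pedigree = build_pedigree(records)
    genotypes = [f"G{i+1:03d}" for i in range(config.n_genotypes)]
    counts = _ramet_counts(config, rng)
    rows = []
    t_idx = 0
    for geno, k in zip(genotypes, counts):
        for _ in range(k):
            t_idx += 1
            rows.append((f"T{t_idx:04d}", geno))
    return pedigree, pd.DataFrame(rows, columns=["tree_id", "genotype_id"])


def simulate_breeding_values(
    A: np.ndarray, G: np.ndarray, rng: np.random.Generator, empirical: bool = False
) -> np.ndarray:
    """q x t breeding values from the matrix-normal MN(0, A, G).

    Equivalent to vec(U) ~ N(0, G (x) A), realised through the Cholesky
    factors of A and G.  With `empirical=True` the latent normals are
    whitened first so that the realized pedigree-metric covariance
    U' A^{-1} U / q equals G *exactly* (the `mvrnorm(empirical=TRUE)`
    convention): parameter-recovery experiments then measure estimation
    error of the pipeline rather than the Monte-Carlo scatter of one
    breeding-value draw, which for 120 genotypes in 34 families would
    dominate the comparison.
    """
    A = np.asarray(A, dtype=float)
    G = np.asarray(G, dtype=float)
    for name, M in (("A", A), ("G", G)):
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise GeneratorError(f"{name} must be square")
        if not np.allclose(M, M.T, atol=1e-8):
            raise GeneratorError(f"{name} must be symmetric")
        wmin = float(np.linalg.eigvalsh(M).min())
        if wmin < -1e-8 * max(1.0, np.abs(M).max()):
            raise GeneratorError(f"{name} is not positive semi-definite (min eig {wmin:.3g})")
    la = safe_cholesky(A)
    lg = safe_cholesky(G)
    q, t = A.shape[0], G.shape[0]
    z = rng.standard_normal((q, t))
    if empirical:
        if q < t:
            raise GeneratorError("empirical moments need at least as many rows as traits")
        lc = safe_cholesky((z.T @ z) / q)
        z = z @ np.linalg.inv(lc).T  # now z' z = q I exactly
    return la @ z @ lg.T


def _induced_seven(G6: np.ndarray) -> np.ndarray:
    """Map a free-trait covariance to the seven-trait space (cd = co3 - bb2)."""
    J = np.zeros((len(TRAITS7), len(FREE_TRAITS)))
    for i, t in enumerate(TRAITS7):
        if t == "cd":
            J[i, FREE_TRAITS.index("co3")] = 1.0
            J[i, FREE_TRAITS.index("bb2")] = -1.0
        else:
            J[i, FREE_TRAITS.index(t)] = 1.0
    return J @ G6 @ J.T


def _truth(config: GeneratorConfig) -> dict:
    """Realized generative parameters on the seven-trait scale."""
    sigma12 = config.cross_year_genetic_covariance()
    nf = len(FREE_TRAITS)
    Gy = sigma12[:nf, :nf]
    Cxy = sigma12[:nf, nf:]
    _, R6 = config.genetic_covariance()
    G7 = _induced_seven(Gy)
    R7 = _induced_seven(R6)
    sd7 = np.sqrt(np.diag(G7))
    corr7 = G7 / np.outer(sd7, sd7)
    h2 = np.diag(G7) / (np.diag(G7) + np.diag(R7))
    # cross-year correlation per trait, including the induced cd row
    j_cd = np.zeros(nf)
    j_cd[FREE_TRAITS.index("co3")] = 1.0
    j_cd[FREE_TRAITS.index("bb2")] = -1.0
    cross = {}
    for t in TRAITS7:
        if t == "cd":
            num = j_cd @ Cxy @ j_cd
            den = j_cd @ Gy @ j_cd
        else:
            i = FREE_TRAITS.index(t)
            num, den = Cxy[i, i], Gy[i, i]
        cross[t] = float(num / den)
    return {
        "traits": TRAITS7,
        "genetic_covariance": G7.tolist(),
        "residual_covariance": R7.tolist(),
        "genetic_correlations": corr7.tolist(),
        "heritability": {t: float(h2[i]) for i, t in enumerate(TRAITS7)},
        "cross_year_genetic_correlation": cross,
        "trait_means": config.trait_means,
        "year_shifts": config.year_shifts,
        "years": list(config.years),
        "n_genotypes": config.n_genotypes,
        "n_trees": config.n_trees,
        "seed": config.seed,
    }


def simulate_phenotypes(
    tree_table: pd.DataFrame,
    pedigree: Pedigree,
    u12: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent milestone days per tree-year plus DBH per tree.

    trait value = trait mean + year shift + genotype breeding value +
    tree-level residual.  The within-tree-year stage ordering
    bb2 < bb4 < co3 < co8 < ls3 (with a safety margin, and with every
    milestone inside its survey window) is enforced by rejection-resampling
    the residual vector; a tree-year that cannot satisfy it within
    `max_rejections` attempts aborts with diagnostics.
    """
    _, R6 = config.genetic_covariance()
    res_sd = np.sqrt(np.diag(R6))
    geno_row = {g: pedigree.genotype_index[g] for g in tree_table["genotype_id"]}
    n_free = len(FREE_TRAITS)
    i_of = {t: i for i, t in enumerate(FREE_TRAITS)}
    sp_lo, sp_hi = config.spring_window
    au_lo, au_hi = config.autumn_window
    margin, gap = config.ordering_margin, config.gap_max
    rows, dbh_rows = [], []
    for tree, geno in tree_table.itertuples(index=False):
        q = geno_row[geno]
        for y_idx, year in enumerate(config.years):
            u = u12[q, y_idx * n_free : (y_idx + 1) * n_free]
            mu = np.array(
                [
                    config.trait_means[t] + (config.year_shifts[t] if y_idx == 1 else 0.0)
                    for t in FREE_TRAITS
                ]
            )
            for attempt in range(config.max_rejections):
                e = rng.standard_normal(n_free) * res_sd
                v = mu + u + e
                bb2, bb4 = v[i_of["bb2"]], v[i_of["bb4"]]
                co3, co8, ls3 = v[i_of["co3"]], v[i_of["co8"]], v[i_of["ls3"]]
                ok = (
                    bb2 >= sp_lo + gap + 1
                    and bb4 >= bb2 + margin
                    and bb4 <= sp_hi - gap - 1
                    and co3 >= au_lo + gap + 7
                    and co8 >= co3 + margin
                    and ls3 >= co8 + margin
                    and ls3 - 10 >= au_lo + gap + 1
                    and ls3 <= au_hi - gap - 1
                )
                if ok:
                    break
            else:
                raise GeneratorError(
                    f"{tree}/{year}: stage ordering unreachable in "
                    f"{config.max_rejections} attempts (windows "
                    f"{config.spring_window}/{config.autumn_window}, mu={mu.round(1)})"
                )
            # intermediate (non-milestone) stages give the survey its full
            # ordinal resolution; drawn inside the milestone brackets
            bb3 = rng.uniform(bb2 + 0.3, bb4 - 0.3)
            bb5 = bb4 + rng.uniform(3.0, 8.0)
            co2 = co3 - rng.uniform(2.0, 6.0)
            co4567 = np.sort(rng.uniform(co3 + 0.3, co8 - 0.3, size=4))
            ls2 = ls3 - rng.uniform(4.0, 10.0)
            rows.append(
                (
                    tree, geno, year,
                    bb2, bb3, bb4, bb5,
                    co2, co3, *co4567, co8,
                    ls2, ls3,
                    co3 - bb2,
                )
            )
            if y_idx == 0:
                dbh = (
                    config.trait_means["dbh"]
                    + u[i_of["dbh"]]
                    + rng.standard_normal() * res_sd[i_of["dbh"]]
                )
                dbh_rows.append((tree, geno, dbh))
    cols = [
        "tree_id", "genotype_id", "year",
        "bb2", "bb3", "bb4", "bb5",
        "co2", "co3", "co4", "co5", "co6", "co7", "co8",
        "ls2", "ls3", "cd",
    ]
    true_days = pd.DataFrame(rows, columns=cols)
    dbh = pd.DataFrame(dbh_rows, columns=["tree_id", "genotype_id", "dbh_cm"])
    return true_days, dbh


def simulate_survey(
    true_days: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ordinal survey rows observing the latent process every 2-5 days.

    At each visit the recorded stage is the highest threshold whose true
    day has passed (piecewise-constant observation).  Spring visits score
    budburst; autumn visits score colouration and leaf senescence.
    """
    thresholds = {
        "bb": ["bb2", "bb3", "bb4", "bb5"],
        "col": ["co2", "co3", "co4", "co5", "co6", "co7", "co8"],
        "ls": ["ls2", "ls3"],
    }
    windows = {"spring": config.spring_window, "autumn": config.autumn_window}
    season_traits = {"spring": ["bb"], "autumn": ["col", "ls"]}
    sp_lo, sp_hi = windows["spring"]
    au_lo, au_hi = windows["autumn"]
    if (
        (true_days["bb2"] < sp_lo).any()
        or (true_days["bb4"] > sp_hi).any()
        or (true_days["co2"] < au_lo).any()
        or (true_days["ls3"] > au_hi).any()
    ):
        raise GeneratorError("survey window too short to contain the true milestone days")
    rows = []
    for rec in true_days.itertuples(index=False):
        for season, (lo, hi) in windows.items():
            day = lo + int(rng.integers(0, 4))
            visits = []
            while day <= hi:
                visits.append(day)
                day += int(rng.integers(config.gap_min, config.gap_max + 1))
            visits = np.array(visits, dtype=float)
            for trait in season_traits[season]:
                days_t = np.array([getattr(rec, c) for c in thresholds[trait]])
                scores = 1 + (visits[:, None] >= days_t[None, :]).sum(axis=1)
                for v, s in zip(visits, scores):
                    rows.append((rec.tree_id, rec.genotype_id, rec.year, int(v), trait, int(s)))
    return pd.DataFrame(
        rows, columns=["tree_id", "genotype_id", "year", "doy", "trait", "score"]
    )


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Full study generation under one seeded generator (byte-reproducible)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    pedigree, tree_table = simulate_crossing_design(config, rng)
    clone_map = clone_incidence(tree_table, pedigree)
    A_full = additive_relationship(pedigree)
    genotypes = sorted(set(tree_table["genotype_id"]))
    A = A_full.submatrix(genotypes)
    # breeding values over the full pedigree (founders included) so the
    # family structure propagates through A
    u12_ped = simulate_breeding_values(
        A_full.values, config.cross_year_genetic_covariance(), rng, empirical=True
    )
    true_days, dbh = simulate_phenotypes(tree_table, pedigree, u12_ped, config, rng)
    survey = simulate_survey(true_days, config, rng)
    trial = LatentTrial(
        pedigree=pedigree,
        clone_map=clone_map,
        tree_table=tree_table,
        relationship=A,
        true_days=true_days,
        dbh=dbh,
        breeding_values=u12_ped,
        truth=_truth(config),
    )
    return SyntheticDataset(trial=trial, survey=survey, config=config)
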