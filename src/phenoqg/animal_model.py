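"""Bayesian multivariate pedigree mixed models ("animal models") by Gibbs
sampling.

Model.  For record i (one tree in one year) with response vector y_i over t
traits:

    y_i = X_i beta + u_{g(i)} + e_i,      e_i ~ N(0, R)
    vec(U) ~ N(0, G (x) A)

where A is the additive relationship matrix among genotypes, G the t x t
genetic covariance, R the t x t residual covariance, and g(i) the genotype
of record i.  Clonal ramets of a genotype are repeated measures of one
genetic effect; among-ramet variation sits in R.  The bivariate cross-year
model uses the two years of one trait as (y1, y2) with an intercept only;
the seven-trait model stacks per-tree-per-year records and adds a fixed
year effect.

Sampler.  A systematic-scan Gibbs cycle with conjugate conditionals:

1. missing responses are drawn from their Gaussian conditionals given the
   observed entries of the same record (data augmentation), which keeps the
   multivariate updates conjugate;
2. (beta, U) are drawn jointly: the generalized eigendecomposition of
   (G, R) rotates the traits to a canonical scale on which residuals are
   iid N(0, 1) and genetic effects independent across canonical traits, so
   each canonical trait is one single-trait mixed-model-equations solve with
   a stochastic right-hand side (one-block Gaussian sampler);
3. G | U ~ InvWishart(nu_g + q,  nu_g V_g + U' A^{-1} U);
4. R | E ~ InvWishart(nu_r + n,  nu_r V_r + E' E).

The prior follows the weak-belief (V, nu) convention: an inverse-Wishart
with scale nu * V and degrees of freedom nu, so nu = 0.002, V = 1 is the
conventional near-flat variance prior.  Fixed effects get an independent
zero-mean prior with precision 1e-8 (effectively flat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import invwishart

from .pedigree import CloneMap, RelationshipMatrix

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Response layout: which traits, and whether year enters as a fixed effect.

    `intercept=False` (a zero-mean model) exists for oracle checks against
    closed-form posteriors; analyses keep the intercept.
    """

    traits: list[str]
    year_effect: bool = False
    intercept: bool = True

    def __post_init__(self) -> None:
        if not self.traits:
            raise ModelError("trait list must be non-empty")


@dataclass
class PriorSpec:
    """Weak-belief inverse-Wishart priors for G and R.

    `v_*` may be a scalar (isotropic scale) or a t x t matrix, e.g. half the
    measured phenotypic covariance.  `nu_*` is the degree of belief; the
    conditional posteriors are proper whenever nu + q (resp. nu + n)
    exceeds t - 1, so nu below t - 1 is allowed.
    """

    v_genetic: float | np.ndarray = 1.0
    nu_genetic: float = 0.002
    v_residual: float | np.ndarray = 1.0
    nu_residual: float = 0.002
    fixed_precision: float = 1e-8

    def scale(self, which: str, t: int) -> np.ndarray:
        v = self.v_genetic if which == "genetic" else self.v_residual
        v = np.asarray(v, dtype=float)
        mat = np.eye(t) * v if v.ndim == 0 else v
        if mat.shape != (t, t):
            raise ModelError(f"{which} prior scale must be scalar or {t}x{t}")
        return mat


@dataclass
class ChainSettings:
    iterations: int = 20_000
    burn_in: int = 2_000
    thinning: int = 20
    seed: int = 20170908

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ModelError("iterations must exceed burn_in")
        if self.thinning < 1:
            raise ModelError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class ModelSystem:
    """Assembled design: responses with missing mask, X, genotype incidence,
    and the cached A inverse."""

    Y: np.ndarray  # n x t, NaN = missing
    X: np.ndarray  # n x p
    geno_idx: np.ndarray  # n, into genotype_ids
    A: np.ndarray  # q x q
    A_inv: np.ndarray
    traits: list[str]
    fixed_names: list[str]
    genotype_ids: list[str]
    record_ids: list[tuple]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        n, t = self.Y.shape
        return n, self.X.shape[1], len(self.genotype_ids), t


@dataclass
class PosteriorDraws:
    """Retained MCMC samples of (G, R, beta, U)."""

    G: np.ndarray  # nd x t x t
    R: np.ndarray
    beta: np.ndarray  # nd x p x t
    u: np.ndarray  # nd x q x t
    traits: list[str]
    fixed_names: list[str]
    genotype_ids: list[str]
    chain: ChainSettings = field(repr=False, default=None)

    @property
    def n_draws(self) -> int:
        return self.G.shape[0]

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise ModelError(f"trait {trait!r} not in model (has {self.traits})")

    def to_frame(self, include_u: bool = False) -> pd.DataFrame:
        """Flat `draw,parameter,value` table (G, R, beta; u on request)."""
        rows = []
        t = len(self.traits)
        for d in range(self.n_draws):
            for i in range(t):
                for j in range(i, t):
                    rows.append((d, f"G[{self.traits[i]},{self.traits[j]}]", self.G[d, i, j]))
                    rows.append((d, f"R[{self.traits[i]},{self.traits[j]}]", self.R[d, i, j]))
            for k, name in enumerate(self.fixed_names):
                for i in range(t):
                    rows.append((d, f"beta[{name},{self.traits[i]}]", self.beta[d, k, i]))
            if include_u:
                for g, gid in enumerate(self.genotype_ids):
                    for i in range(t):
                        rows.append((d, f"u[{gid},{self.traits[i]}]", self.u[d, g, i]))
        return pd.DataFrame(rows, columns=["draw", "parameter", "value"])


def assemble_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    clone_map: CloneMap,
    A: RelationshipMatrix,
) -> ModelSystem:
    """Build the model system from wide per-record trait columns.

    `records` carries one row per record (tree, or tree-year when
    `spec.year_effect`), columns `tree_id`, `genotype_id`, optionally
    `year`, plus one column per trait (NaN = missing).  Records are sorted
    canonically by (tree_id, year) so the sampler's draws do not depend on
    input row order.
    """
    for trait in spec.traits:
        if trait not in records.columns:
            raise ModelError(f"records lack trait column {trait!r}")
    sort_cols = ["tree_id"] + (["year"] if "year" in records.columns else [])
    records = records.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    Y = records[spec.traits].to_numpy(dtype=float)
    all_missing = np.isnan(Y).all(axis=1)
    if all_missing.any():
        raise ModelError(
            f"{int(all_missing.sum())} records have every response missing; drop them first"
        )
    unknown_tree = ~records["tree_id"].astype(str).isin(clone_map.tree_to_genotype)
    if unknown_tree.any():
        raise ModelError("records reference trees absent from the clone map")
    geno = records["tree_id"].astype(str).map(clone_map.tree_to_genotype)
    gid_index = {g: i for i, g in enumerate(A.ids)}
    missing_geno = sorted(set(geno) - set(gid_index))
    if missing_geno:
        raise ModelError(f"genotypes absent from A: {missing_geno}")
    geno_idx = geno.map(gid_index).to_numpy(dtype=int)
    cols = []
    fixed_names = []
    if spec.intercept:
        cols.append(np.ones(len(records)))
        fixed_names.append("intercept")
    if spec.year_effect:
        if "year" not in records.columns:
            raise ModelError("year_effect requested but records have no year column")
        years = sorted(records["year"].unique())
        for y in years[1:]:
            cols.append((records["year"] == y).to_numpy(dtype=float))
            fixed_names.append(f"year{y}")
    X = np.column_stack(cols) if cols else np.zeros((len(records), 0))
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed design is rank deficient")
    record_ids = list(
        records[sort_cols].itertuples(index=False, name=None)
    )
    return ModelSystem(
        Y=Y,
        X=X,
        geno_idx=geno_idx,
        A=A.values,
        A_inv=np.linalg.inv(A.values),
        traits=list(spec.traits),
        fixed_names=fixed_names,
        genotype_ids=list(A.ids),
        record_ids=record_ids,
    )


def _draw_invwishart(scale: np.ndarray, df: float, rng) -> np.ndarray:
    """IW draw with a one-shot jitter retry on a non-PD scale."""
    scale = 0.5 * (scale + scale.T)
    try:
        np.linalg.cholesky(scale)
    except np.linalg.LinAlgError:
        logger.warning("non-PD conditional scale; jittering by 1e-8 I")
        scale = scale + 1e-8 * np.eye(len(scale))
        np.linalg.cholesky(scale)  # abort loudly if still bad
    draw = invwishart.rvs(df=df, scale=scale, random_state=rng)
    return np.atleast_2d(draw)


def _missing_patterns(Y: np.ndarray):
    """Group record indices by their missingness pattern (skip complete rows)."""
    mask = np.isnan(Y)
    patterns = {}
    for i, row in enumerate(mask):
        if row.any():
            patterns.setdefault(tuple(row), []).append(i)
    return [
        (np.array(rows), np.nonzero(pat)[0], np.nonzero(~np.array(pat))[0])
        for pat, rows in patterns.items()
    ]


def gibbs_run(
    system: ModelSystem,
    priors: PriorSpec | None = None,
    chain: ChainSettings | None = None,
    sample_residual: bool = True,
    fixed_residual: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return the retained draws.

    `sample_residual=False` freezes R at `fixed_residual` (for conjugate
    oracle checks where the residual covariance is known).  All randomness
    comes from one generator seeded by `chain.seed`; together with the
    canonical record ordering this makes retained draws exactly reproducible
    and invariant to input record permutation.
    """
    priors = priors or PriorSpec()
    chain = chain or ChainSettings()
    n, p, q, t = system.shape
    rng = np.random.default_rng(chain.seed)
    Vg = priors.scale("genetic", t)
    Vr = priors.scale("residual", t)

    X, geno_idx, A_inv = system.X, system.geno_idx, system.A_inv
    XtX = X.T @ X + priors.fixed_precision * np.eye(p)
    if p:
        XtZ = np.vstack(
            [np.bincount(geno_idx, weights=X[:, j], minlength=q) for j in range(p)]
        )
    else:
        XtZ = np.zeros((0, q))
    counts = np.bincount(geno_idx, minlength=q).astype(float)

    Y = system.Y.copy()
    col_means = np.nanmean(Y, axis=0)
    patterns = _missing_patterns(system.Y)
    for rows, miss, _ in patterns:
        Y[np.ix_(rows, miss)] = col_means[miss]

    col_var = np.nanvar(system.Y, axis=0)
    col_var[col_var <= 0] = 1.0
    G = np.diag(0.5 * col_var)
    if fixed_residual is not None:
        R = np.atleast_2d(np.asarray(fixed_residual, dtype=float)).copy()
    else:
        R = np.diag(0.5 * col_var)
    beta = np.zeros((p, t))
    U = np.zeros((q, t))

    nd = chain.n_retained
    out_G = np.empty((nd, t, t))
    out_R = np.empty((nd, t, t))
    out_beta = np.empty((nd, p, t))
    out_u = np.empty((nd, q, t))
    kept = 0

    for it in range(chain.iterations):
        # (1) data augmentation of missing responses
        if patterns:
            mu_full = X @ beta + U[geno_idx]
            for rows, miss, obs in patterns:
                R_oo = R[np.ix_(obs, obs)]
                R_mo = R[np.ix_(miss, obs)]
                R_mm = R[np.ix_(miss, miss)]
                if obs.size:
                    co = cho_factor(R_oo, lower=True)
                    gain = cho_solve(co, R_mo.T).T  # R_mo R_oo^-1
                    resid = Y[np.ix_(rows, obs)] - mu_full[np.ix_(rows, obs)]
                    cond_mean = mu_full[np.ix_(rows, miss)] + resid @ gain.T
                    cond_cov = R_mm - gain @ R_mo.T
                else:
                    cond_mean = mu_full[np.ix_(rows, miss)]
                    cond_cov = R_mm
                try:
                    L = np.linalg.cholesky(cond_cov)
                except np.linalg.LinAlgError:
                    L = np.linalg.cholesky(cond_cov + 1e-8 * np.eye(len(miss)))
                z = rng.standard_normal((rows.size, miss.size))
                Y[np.ix_(rows, miss)] = cond_mean + z @ L.T

        # (2) canonical transformation and the joint location draw
        try:
            w, M = sla.eigh(G, R)
        except np.linalg.LinAlgError:
            logger.warning("generalized eigendecomposition failed; jittering G, R")
            w, M = sla.eigh(G + 1e-8 * np.eye(t), R + 1e-8 * np.eye(t))
        w = np.clip(w, 1e-12, None)
        Ystar = Y @ M
        beta_star = np.empty((p, t))
        u_star = np.empty((q, t))
        for j in range(t):
            C = np.empty((p + q, p + q))
            C[:p, :p] = XtX
            C[:p, p:] = XtZ
            C[p:, :p] = XtZ.T
            C[p:, p:] = A_inv / w[j]
            C[p:, p:][np.diag_indices(q)] += counts
            rhs = np.empty(p + q)
            rhs[:p] = X.T @ Ystar[:, j]
            rhs[p:] = np.bincount(geno_idx, weights=Ystar[:, j], minlength=q)
            cf = cho_factor(C, lower=True)
            theta = cho_solve(cf, rhs) + solve_triangular(
                cf[0].T, rng.standard_normal(p + q), lower=False
            )
            beta_star[:, j] = theta[:p]
            u_star[:, j] = theta[p:]
        M_inv = np.linalg.inv(M)
        beta = beta_star @ M_inv
        U = u_star @ M_inv

        # (3) genetic covariance
        S_g = priors.nu_genetic * Vg + U.T @ A_inv @ U
        G = _draw_invwishart(S_g, priors.nu_genetic + q, rng)

        # (4) residual covariance
        if sample_residual:
            E = Y - X @ beta - U[geno_idx]
            S_r = priors.nu_residual * Vr + E.T @ E
            R = _draw_invwishart(S_r, priors.nu_residual + n, rng)

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thinning == 0 and kept < nd:
            out_G[kept] = G
            out_R[kept] = R
            out_beta[kept] = beta
            out_u[kept] = U
            kept += 1

    return PosteriorDraws(
        G=out_G[:kept],
        R=out_R[:kept],
        beta=out_beta[:kept],
        u=out_u[:kept],
        traits=system.traits,
        fixed_names=system.fixed_names,
        genotype_ids=system.genotype_ids,
        chain=chain,
    )


def prior_sensitivity(
    system: ModelSystem,
    prior_list: list[PriorSpec],
    chain: ChainSettings | None = None,
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """Posterior medians of h2 and genetic correlations under each prior.

    Returns one row per parameter with a `max_diff` column and a `flagged`
    flag where medians differ by more than `tolerance` between priors —
    prior dominance, expected at small q, is what the flag surfaces.
    """
    if len(prior_list) < 2:
        raise ModelError("need at least two priors to compare")
    chain = chain or ChainSettings()
    t = len(system.traits)
    medians: dict[str, list[float]] = {}
    for k, prior in enumerate(prior_list):
        draws = gibbs_run(system, prior, chain)
        dG, dR = draws.G, draws.R
        for i in range(t):
            name = f"h2[{system.traits[i]}]"
            series = dG[:, i, i] / (dG[:, i, i] + dR[:, i, i])
            medians.setdefault(name, []).append(float(np.median(series)))
            for j in range(i + 1, t):
                rname = f"r[{system.traits[i]},{system.traits[j]}]"
                r = dG[:, i, j] / np.sqrt(dG[:, i, i] * dG[:, j, j])
                medians.setdefault(rname, []).append(float(np.median(r)))
    rows = []
    for name, vals in medians.items():
        spread = max(vals) - min(vals)
        rows.append((name, *vals, spread, spread > tolerance))
    cols = (
        ["parameter"]
        + [f"prior{k}" for k in range(len(prior_list))]
        + ["max_diff", "flagged"]
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# record assembly from transition tables


def bivariate_records(
    transition_table: pd.DataFrame, stage: str
) -> tuple[pd.DataFrame, ModelSpec]:
    """Per-tree records with one trait's two years as a bivariate response."""
    sub = transition_table[transition_table["stage"] == stage]
    if sub.empty:
        raise ModelError(f"stage {stage!r} absent from transition table")
    wide = sub.pivot(
        index=["tree_id", "genotype_id"], columns="year", values="doy"
    ).reset_index()
    years = [c for c in wide.columns if c not in ("tree_id", "genotype_id")]
    traits = [f"{stage}_{y}" for y in years]
    wide.columns = ["tree_id", "genotype_id"] + traits
    wide = wide.dropna(how="all", subset=traits)
    return wide, ModelSpec(traits=traits, year_effect=False)


def stacked_records(
    transition_table: pd.DataFrame,
    canopy: pd.DataFrame | None = None,
    dbh: pd.DataFrame | None = None,
    dbh_year: int | None = None,
) -> tuple[pd.DataFrame, ModelSpec]:
    """Per-tree-per-year records for the seven-trait model.

    Phenology milestones come from the transition table, CD from `canopy`
    (cd_days), and DBH — measured once — joins the record of its
    measurement year only (the earliest year by default) and is missing
    elsewhere.
    """
    wide = transition_table.pivot(
        index=["tree_id", "genotype_id", "year"], columns="stage", values="doy"
    ).reset_index()
    traits = [c for c in wide.columns if c not in ("tree_id", "genotype_id", "year")]
    if canopy is not None:
        wide = wide.merge(
            canopy.rename(columns={"cd_days": "cd"}),
            on=["tree_id", "genotype_id", "year"],
            how="left",
        )
        traits.append("cd")
    if dbh is not None:
        if dbh_year is None:
            dbh_year = int(wide["year"].min())
        dbh_col = dbh.rename(columns={"dbh_cm": "dbh"})[["tree_id", "dbh"]]
        wide = wide.merge(dbh_col, on="tree_id", how="left")
        wide.loc[wide["year"] != dbh_year, "dbh"] = np.nan
        traits.append("dbh")
    wide = wide.dropna(how="all", subset=traits)
    return wide, ModelSpec(traits=traits, year_effect=True)
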