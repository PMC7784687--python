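"""Independent oracles used by the test suite.

These deliberately avoid the package's own computational paths: the
gene-dropping oracle estimates additive relationships by simulating allele
transmission, and the conjugate-posterior helper gives the closed-form
moments of an inverse-Wishart (here inverse-gamma) posterior.
"""

from __future__ import annotations

import numpy as np


def gene_drop_relationship(parent_pairs, n_drops=100_000, seed=0):
    """Monte-Carlo additive relationship matrix by gene dropping.

    `parent_pairs` is an ordered list of (sire_index, dam_index) with None
    for founders, parents before offspring.  Each founder receives two
    unique alleles; every offspring inherits one random allele from each
    parent.  The additive relationship is twice the kinship coefficient,
    estimated as the average IBD indicator between one allele drawn from
    each individual:

        A[i, j] ~= mean over drops of
                   (1/2) * sum_{a in i, b in j} 1[a IBD b] / 2

    Returns (A_hat, se) where se is the per-entry Monte-Carlo standard
    error of the mean.
    """
    rng = np.random.default_rng(seed)
    n = len(parent_pairs)
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    next_allele = 0
    for i, pair in enumerate(parent_pairs):
        if pair is None:
            alleles[i, 0] = next_allele
            alleles[i, 1] = next_allele + 1
            next_allele += 2
        else:
            s, d = pair
            pick_s = rng.integers(0, 2, n_drops)
            pick_d = rng.integers(0, 2, n_drops)
            alleles[i, 0] = alleles[s, pick_s, np.arange(n_drops)]
            alleles[i, 1] = alleles[d, pick_d, np.arange(n_drops)]
    A_hat = np.empty((n, n))
    se = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = np.zeros(n_drops)
            for a in range(2):
                for b in range(2):
                    ibd += alleles[i, a] == alleles[j, b]
            stat = ibd / 2.0  # per-drop estimate of A[i, j]
            A_hat[i, j] = A_hat[j, i] = stat.mean()
            se[i, j] = se[j, i] = stat.std(ddof=1) / np.sqrt(n_drops)
    return A_hat, se


def invgamma_posterior_moments(y, prior_scale, prior_df):
    """Closed-form posterior mean/variance of a variance parameter.

    For y_i | v ~ N(0, v) and v ~ InvWishart_1(df0, s0) (density
    |v|^-(df0+2)/2 exp(-s0 / 2v)), the posterior is
    InvWishart_1(df0 + n, s0 + sum y^2) with

        E[v]   = scale / (df - 2)
        Var[v] = 2 scale^2 / ((df - 2)^2 (df - 4))
    """
    y = np.asarray(y, dtype=float)
    scale = prior_scale + float(y @ y)
    df = prior_df + len(y)
    mean = scale / (df - 2)
    var = 2 * scale**2 / ((df - 2) ** 2 * (df - 4))
    return mean, var
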