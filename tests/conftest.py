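"""Shared fixtures: one default synthetic study and the fitted models that
several test modules (including the acceptance tests) reuse."""

from __future__ import annotations

import numpy as np
import pytest

import phenoqg as pq


@pytest.fixture(scope="session")
def dataset() -> pq.SyntheticDataset:
    """The default synthetic study (study-design counts, default seed)."""
    return pq.generate_dataset()


@pytest.fixture(scope="session")
def transition_table(dataset):
    return pq.build_transition_table(dataset.survey)


@pytest.fixture(scope="session")
def canopy(transition_table):
    return pq.canopy_duration(transition_table)


@pytest.fixture(scope="session")
def seven_trait_draws(dataset, transition_table, canopy):
    """Seven-trait multivariate fit on the default study, scaled-down chain."""
    records, spec = pq.stacked_records(transition_table, canopy, dataset.trial.dbh)
    system = pq.assemble_design(
        records, spec, dataset.trial.clone_map, dataset.trial.relationship
    )
    v = np.diag(np.nanvar(system.Y, axis=0)) / 2
    priors = pq.PriorSpec(v_genetic=v, v_residual=v)
    return pq.gibbs_run(system, priors, pq.ChainSettings())


@pytest.fixture(scope="session")
def dbh_draws(dataset):
    """Univariate animal model for lifetime growth (DBH)."""
    records = dataset.trial.dbh.rename(columns={"dbh_cm": "dbh"})
    system = pq.assemble_design(
        records,
        pq.ModelSpec(traits=["dbh"]),
        dataset.trial.clone_map,
        dataset.trial.relationship,
    )
    return pq.gibbs_run(system, pq.PriorSpec(), pq.ChainSettings())


@pytest.fixture(scope="session")
def co8_cross_year_fits():
    """Bivariate cross-year experiment: co8 simulated with generative
    cross-year genetic correlation 0.6 and per-year heritability 0.5.

    Three replicate trials are generated and fitted; recovery is judged on
    the replicate-averaged posterior median, the same experimental design
    the acceptance script uses (single-replicate medians carry ~0.07
    residual-sampling scatter at the study's size)."""
    fits = []
    for k in range(3):
        config = pq.GeneratorConfig().with_overrides(
            cross_year_r={t: 0.6 for t in pq.FREE_TRAITS},
            heritability={"co8": 0.5},
            seed=20170908 + k,
        )
        ds = pq.generate_dataset(config)
        table = pq.build_transition_table(ds.survey)
        records, spec = pq.bivariate_records(table, "co8")
        system = pq.assemble_design(
            records, spec, ds.trial.clone_map, ds.trial.relationship
        )
        draws = pq.gibbs_run(
            system, pq.PriorSpec(), pq.ChainSettings(seed=20170908 + 10 * k)
        )
        fits.append((ds, draws, spec))
    return fits
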