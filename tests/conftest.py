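"""Shared expensive fixtures, all session-scoped and deterministically seeded.

Every seed below is a fixed literal: the whole suite is reproducible
bit-for-bit, and nothing is sampled at collection time.
"""

from __future__ import annotations

import numpy as np
import pytest

import bifax as bx


@pytest.fixture(scope="session")
def pool08():
    """55 MC + 3 CR bi-factor pool with implied disattenuated rho ~ 0.80."""
    return bx.generate_item_pool(bx.GeneratorConfig(target_rho=0.8, seed=1))


@pytest.fixture(scope="session")
def responses08(pool08):
    """50 ability triples and their simulated 58-item response patterns."""
    thetas = bx.sample_thetas(50, 123)
    return thetas, bx.simulate_responses(pool08, thetas, 456)


@pytest.fixture(scope="session")
def maps08(pool08, responses08):
    """Batch bi-factor MAP estimates for the 50 shared patterns."""
    _, responses = responses08
    return bx.map_bifactor_batch(responses, pool08)


@pytest.fixture(scope="session")
def unidim_recovery():
    """EM recovery run: 27 MC + 3 CR unidimensional truth, n = 2,000.

    Returns (true item set, true abilities, responses, CalibrationResult).
    """
    rng = np.random.default_rng(314)
    mc = tuple(
        bx.UnidimMCItem(a=float(a), b=float(b), g=float(g))
        for a, b, g in zip(rng.uniform(0.7, 2.2, 27),
                           rng.normal(0.0, 1.0, 27),
                           rng.uniform(0.05, 0.30, 27))
    )
    cr = []
    for _ in range(3):
        first = float(rng.normal(-1.2, 0.4))
        thr = first + np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 1.0, 3))])
        cr.append(bx.UnidimCRItem(a=float(rng.uniform(0.7, 2.2)),
                                  thresholds=tuple(thr)))
    items = bx.UnidimItemSet(mc, tuple(cr), n_categories=5)
    theta = np.random.default_rng(315).standard_normal(2_000)
    responses = bx.simulate_responses(items, theta, 316)
    fit = bx.calibrate_unidimensional(responses)
    return items, theta, responses, fit


@pytest.fixture(scope="session")
def bifactor_recovery():
    """Reduced-scale MCMC recovery: 20 MC + 3 CR pool, n = 1,500.

    Returns (true pool, CalibrationResult).
    """
    pool = bx.generate_item_pool(
        bx.GeneratorConfig(target_rho=0.85, seed=3, n_mc=20, n_cr=3))
    thetas = bx.sample_thetas(1_500, 5)
    responses = bx.simulate_responses(pool, thetas, 6)
    fit = bx.calibrate_bifactor(
        responses,
        mcmc=bx.McmcConfig(n_cycles=6_000, n_burnin=1_000, thin_interval=5,
                           seed=11),
    )
    return pool, fit


@pytest.fixture(scope="session")
def trend_report():
    """Desk-scale three-condition study, rho targets 0.78 / 0.89 / 0.96."""
    config = bx.StudyConfig(
        conditions=(bx.GeneratorConfig(target_rho=0.78),
                    bx.GeneratorConfig(target_rho=0.89),
                    bx.GeneratorConfig(target_rho=0.96)),
        calibration_n=2_000,
        n_simulees=5_000,
        n_replications=20,
        mcmc=bx.McmcConfig(n_cycles=3_000, n_burnin=600, thin_interval=4),
        master_seed=0,
        truth="estimated",
    )
    return bx.run_study(config)


@pytest.fixture(scope="session")
def degenerate_report():
    """Unidimensional-truth study: all specific loadings zero (rho = 1)."""
    config = bx.StudyConfig(
        conditions=(bx.GeneratorConfig(target_rho=1.0),),
        calibration_n=2_000,
        n_simulees=5_000,
        n_replications=20,
        truth="generator",
        master_seed=7,
    )
    return bx.run_study(config)
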