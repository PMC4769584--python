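"""Shared fixtures.

The two session-scoped "study" fixtures run the full simulation-and-fit
pipeline at the desk-scale study conditions (2 x 1000 training individuals,
10,000 variants, 200 tiered QTL, h^2 = 0.6) and are shared by every test
that interrogates calibration, architecture recovery or prediction accuracy,
so the expensive chains run once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from bayesrc import (
    SimulationConfig,
    accuracy_and_bias,
    evaluate_prediction,
    fit_bayesr,
    fit_bayesrc,
    gblup_fit,
    simulate_dataset,
    standardize,
)

TRAIT1_SEEDS = (1, 2, 3, 4, 5)
UNIFORM_SEEDS = (1, 2, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast candidate-gene simulation used by unit tests."""
    return SimulationConfig(
        n_per_population=(60, 60),
        n_validation_per_population=(20, 20),
        n_variants=400,
        ld_block_length=8,
        n_qtl_per_tier=(10, 4, 1),
        n_candidate_genes=12,
        gene_length_variants=8,
        gene_window_variants=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config)


def _fit_one_seed(seed: int, qtl_placement: str | None, n_iter: int, burn_in: int,
                  rc_chains: int, with_comparators: bool) -> dict:
    cfg = SimulationConfig(seed=seed, qtl_placement=qtl_placement)
    ds = simulate_dataset(cfg)
    g_tr = ds.genotypes.subset_individuals(ds.train_index)
    g_val = ds.genotypes.subset_individuals(ds.val_index)
    design = standardize(g_tr)
    W_val = design.transform(g_val.dosages)
    ptr = ds.training_phenotypes()
    ref = ds.truth.genetic_values[ds.val_index]

    rc = fit_bayesrc(
        ptr, design, ds.classes, h2=0.6, n_iter=n_iter, burn_in=burn_in,
        n_chains=rc_chains, seed=seed, genotypes=g_tr,
    )
    r = fit_bayesr(
        ptr, design, h2=0.6, n_iter=n_iter, burn_in=burn_in,
        n_chains=1, seed=seed, genotypes=g_tr,
    )
    out = {
        "seed": seed,
        "truth_mask": ds.truth.is_qtl_mask(cfg.n_variants),
        "true_tier_counts": np.array(cfg.n_qtl_per_tier),
        "pip_rc": rc.pip,
        "est_component_counts": rc.class_component_counts.sum(axis=0),
        "acc_rc": evaluate_prediction(W_val, rc, ref).accuracy,
        "acc_r": evaluate_prediction(W_val, r, ref).accuracy,
        "summary_rc": rc,
        "classes": ds.classes,
    }
    if with_comparators:
        gb = gblup_fit(ptr, design, h2=0.6)
        out["acc_gblup"] = accuracy_and_bias(W_val @ gb.vbar, ref)[0]
    return out


@pytest.fixture(scope="session")
def trait1_study():
    """Candidate-gene (enriched-class) simulations at the study conditions:
    5 seeds, BayesRC with 3 chains x 5000 iterations (2500 burn-in), BayesR
    and GBLUP comparators on the held-out validation split."""
    return [
        _fit_one_seed(s, None, n_iter=5000, burn_in=2500, rc_chains=3,
                      with_comparators=True)
        for s in TRAIT1_SEEDS
    ]


@pytest.fixture(scope="session")
def uniform_qtl_study():
    """Uniform-QTL simulations (no class is enriched) with the same informed
    class definitions, for the no-penalty property."""
    return [
        _fit_one_seed(s, "uniform", n_iter=3000, burn_in=1500, rc_chains=1,
                      with_comparators=False)
        for s in UNIFORM_SEEDS
    ]
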