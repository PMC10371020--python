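"""Shared fixtures: synthetic datasets and heavyweight model fits reused
across test modules (session-scoped so each expensive fit runs once)."""

from __future__ import annotations

import numpy as np
import pytest

from rloopscape.counts import size_factors_from_spike
from rloopscape.enrich import EnrichmentOptions, fit_enrichment
from rloopscape.simulate import (
    EnrichmentEffects,
    SimConfig,
    build_ground_truth,
    simulate_counts,
    simulate_expression,
    simulate_genome_annotation,
)

RECOVERY_SEED = 20230726  # fixed study seed for parameter-recovery checks


def make_simulation(cfg: SimConfig):
    features, rep, mask = simulate_genome_annotation(cfg)
    expression = simulate_expression(cfg, features)
    truth = build_ground_truth(cfg, features, expression)
    counts = simulate_counts(cfg, truth)
    return {
        "cfg": cfg, "features": features, "rep": rep, "mask": mask,
        "expression": expression, "truth": truth, "counts": counts,
    }


@pytest.fixture(scope="session")
def recovery_sim():
    """200-kb single-genotype dataset with planted enrichment structure."""
    cfg = SimConfig(seed=RECOVERY_SEED, genotypes=("WT",), differential_regions=())
    sim = make_simulation(cfg)
    sim["counts"].size_factors = size_factors_from_spike(sim["counts"])
    return sim


@pytest.fixture(scope="session")
def recovery_posteriors(recovery_sim):
    opts = EnrichmentOptions(seed=RECOVERY_SEED + 1)
    return {
        s: fit_enrichment(recovery_sim["counts"], "WT", s, opts) for s in "+-"
    }


@pytest.fixture(scope="session")
def null_sim():
    """Same measurement model with all planted enrichment effects at zero."""
    cfg = SimConfig(
        seed=RECOVERY_SEED + 2,
        genotypes=("WT",),
        enrichment_effects=EnrichmentEffects(
            feature_effect={k: 0.0 for k in ("CDS", "UTR5", "UTR3", "ncRNA", "rRNA", "tRNA")},
            expression_slope={"WT": 0.0},
            orientation_effect=0.0,
            interaction_effect=0.0,
        ),
        differential_regions=(),
    )
    sim = make_simulation(cfg)
    sim["counts"].size_factors = size_factors_from_spike(sim["counts"])
    return sim


@pytest.fixture(scope="session")
def null_posterior(null_sim):
    opts = EnrichmentOptions(seed=RECOVERY_SEED + 3)
    return fit_enrichment(null_sim["counts"], "WT", "+", opts)


@pytest.fixture(scope="session")
def indel_recovery_fit():
    """Poisson regression recovery: planted hybrid effect 0.5 on indels."""
    from rloopscape.mutation import fit_mutation_regression
    from rloopscape.simulate import simulate_regression_table

    coeffs = {
        "indel": {"z_rdh": 0.5, "z_expr": 0.0, "head_on": 0.0,
                  "head_on:z_rdh": 0.0, "head_on:z_expr": 0.0}
    }
    table = simulate_regression_table(
        1000, coeffs, mean_count=2.0, seed=RECOVERY_SEED + 4
    )
    fit = fit_mutation_regression(table, "indel", draws=4000, seed=RECOVERY_SEED + 5)
    return table, fit


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
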