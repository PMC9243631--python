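from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

import tribe_edit as te

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_run():
    """Full default bulk simulation run through the whole pipeline.

    Shared across tests: 1,000 genes, 150 candidate positions each (5
    edited), triplicate three-condition design at depth 100.
    """
    cfg = te.SimConfig(rng_seed=1)
    counts, expression, truth = te.simulate_bulk_counts(cfg)
    variants = te.call_variant_positions(counts)
    sites = te.site_counts_for_genes(counts, variants)
    results = te.differential_editing_test(sites)
    return SimpleNamespace(
        config=cfg,
        counts=counts,
        expression=expression,
        truth=truth,
        variants=variants,
        sites=sites,
        results=results,
    )


@pytest.fixture(scope="session")
def small_run():
    """Small, fast bulk simulation for structural tests."""
    cfg = te.SimConfig(
        n_genes=40, positions_per_gene=30, edited_sites_per_gene=3, rng_seed=9
    )
    counts, expression, truth = te.simulate_bulk_counts(cfg)
    return SimpleNamespace(config=cfg, counts=counts, expression=expression, truth=truth)


@pytest.fixture(scope="session")
def sc_panel():
    """Reduced-panel single-cell simulation (300 shallow cells)."""
    cfg = te.SimConfig(
        n_genes=100,
        positions_per_gene=40,
        edited_sites_per_gene=5,
        n_cells=300,
        cell_depth_mean=2.0,
        rng_seed=7,
    )
    sc_counts, cells, truth = te.simulate_single_cell_counts(cfg)
    return SimpleNamespace(config=cfg, counts=sc_counts, cells=cells, truth=truth)
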