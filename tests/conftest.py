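"""Shared fixtures: a small simulated cohort reused across the unit suite."""

import numpy as np
import pandas as pd
import pytest

import del5q


def small_config(**overrides):
    base = dict(
        seed=12345,
        n_samples=2,
        cells_per_sample=400,
        del_fraction_per_sample=(0.4, 0.7),
        n_reference_samples=1,
        reference_cells_per_sample=400,
        n_genes=600,
        n_region_genes=90,
        n_snps_region=60,
        n_snps_flank=60,
        n_cell_types=6,
    )
    base.update(overrides)
    return del5q.SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """Default small cohort with a real deletion (dosage 0.5)."""
    return del5q.simulate(small_config())


@pytest.fixture(scope="session")
def normed(cohort):
    return del5q.normalize_log(cohort.counts)


@pytest.fixture(scope="session")
def channel_calls(cohort, normed):
    """Both channels + consensus on the small cohort, merged with truth."""
    # k scaled down with the cohort so clusters keep >= ~30 members,
    # matching the cells-per-cluster regime the channel is tuned for
    expr = del5q.expression_channel(
        normed, cohort.meta, cohort.genome, k=12, seed=0
    )
    al = del5q.allele_channel(cohort.alleles, normed, cohort.meta, cohort.genome)
    calls = del5q.combine(expr.calls, al.calls)
    return calls.merge(
        cohort.meta[["cell_id", "sample_id", "cell_type", "truth_genotype"]],
        on="cell_id",
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no deletion anywhere (both channels should stay quiet)."""
    return del5q.simulate(
        small_config(seed=54321, del_fraction_per_sample=(0.0, 0.0))
    )


def brute_force_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exact enumeration over the hypergeometric support."""
    from math import comb

    total = comb(N, n)
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(max(k, max(0, n - (N - K))), min(n, K) + 1)
    ) / total
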