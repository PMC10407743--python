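"""Shared fixtures: small planted cohorts and their derived tables.

Session scope keeps the expensive builds (feature assembly, preprocessing,
cross-validation) to one run each; every fixture is generated from a fixed
seed so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tracegene.cohort import CohortConfig, EffectSizes, generate_cohort
from tracegene.pipeline import build_feature_table, cohort_labels
from tracegene.preprocess import TracePreprocessor


SMALL_TISSUES = ("liver", "brain", "skin")


def small_config(seed: int = 1, **overrides) -> CohortConfig:
    kwargs = dict(
        n_genes=500,
        tissues=SMALL_TISSUES,
        samples_per_tissue=10,
        positives_per_tissue=30,
        frac_disease_genes=0.3,
        n_go_terms=40,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_features(small_bundle):
    table, ctx = build_feature_table(small_bundle, seed=1)
    return table, ctx


@pytest.fixture(scope="session")
def small_processed(small_features):
    table, _ = small_features
    pre = TracePreprocessor(seed=1)
    processed = pre.fit_transform(table)
    return processed, pre


@pytest.fixture(scope="session")
def small_labels(small_bundle, small_features):
    table, _ = small_features
    return cohort_labels(small_bundle, table.genes)


def random_count_matrix(n_genes: int, tissues: dict[str, int], seed: int):
    """Random counts with a tissue map, for oracle comparisons."""
    from tracegene.expression import CountMatrix

    rng = np.random.default_rng(seed)
    samples, tissue_of = [], []
    for t, n in tissues.items():
        for i in range(n):
            samples.append(f"{t}_{i}")
            tissue_of.append(t)
    base = rng.lognormal(2.5, 1.5, size=(n_genes, 1))
    counts = rng.poisson(base * rng.uniform(0.5, 2.0, size=(1, len(samples))))
    genes = [f"g{i:04d}" for i in range(n_genes)]
    values = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(values=values, tissue_of=pd.Series(tissue_of, index=samples))
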