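"""Shared fixtures: a reduced-scale synthetic dataset used across tests.

The reduced generator keeps every planted effect (pairs, low-expression
genes, read-through, PROMPT extension, SEs, proteomics) at 1/5 of the full
cohort size so module tests stay fast; full-scale recovery runs in the
acceptance suite.
"""

import numpy as np
import pytest

from promptscan.genome_intervals import AnalysisParams
from promptscan.synthetic_data import (
    SyntheticSpec,
    make_annotation,
    make_genome,
    simulate_coverage,
)


def small_spec_kwargs(seed: int = 0) -> dict:
    return dict(
        seed=seed,
        n_chroms=2,
        chrom_length=600_000,
        n_genes=40,
        n_se=24,
        n_de_genes=4,
        n_upstream_contaminated=3,
        proteomics_n=80,
        proteomics_n_depleted=4,
    )


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(**small_spec_kwargs())


@pytest.fixture(scope="session")
def small_data(small_spec):
    genes, truth = make_annotation(small_spec)
    cov_c = simulate_coverage(small_spec, genes, truth, "control")
    cov_d = simulate_coverage(small_spec, genes, truth, "depleted")
    return small_spec, genes, truth, cov_c, cov_d


@pytest.fixture(scope="session")
def small_genome(small_data):
    spec, genes, truth, _, _ = small_data
    genome, manifest = make_genome(spec, genes, truth)
    return genome, manifest


@pytest.fixture()
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
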