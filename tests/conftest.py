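"""Shared fixtures.

The heavier end-to-end fixtures are session-scoped and use a reduced bundle
(160 genes on 2 x 2 Mb, 12 cofactor PWMs) so the whole suite stays well
inside a desktop-CPU budget; the generator's full-size defaults are exercised
separately in the synthetic-data unit tests.
"""

import numpy as np
import pytest

from cobind.pipeline import PipelineParams, analyze_bundle
from cobind.synth import SyntheticConfig, generate_bundle


def small_config(seed: int = 1, **overrides) -> SyntheticConfig:
    kw = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length=2_000_000,
        n_genes=160,
        n_cofactors=12,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


def tiny_config(seed: int = 1, **overrides) -> SyntheticConfig:
    kw = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length=1_200_000,
        n_genes=100,
        n_cofactors=8,
        n_filtered_cofactors=2,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def bundle():
    return generate_bundle(small_config(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return analyze_bundle(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
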