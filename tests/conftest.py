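import numpy as np
import pytest
from hypothesis import settings

import etanet as e

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


SINGLE_SITE_SPEC = e.FixtureSpec(seed=7)
TWO_SITE_SPEC = e.FixtureSpec(seed=7, sites_per_protein=2, corrupt_primary_fraction=0.25)
SMALL_SPEC = e.FixtureSpec(n_proteins=8, n_functions=2, decoy_residues=12, seed=3)


@pytest.fixture(scope="session")
def single_bench():
    """20 proteins, 4 functions, one planted site each, 0.2 Å jitter."""
    return e.generate_benchmark(SINGLE_SITE_SPEC)


@pytest.fixture(scope="session")
def single_model(single_bench):
    return e.train_svm(e.generate_svm_training(single_bench, seed=1), seed=1)


@pytest.fixture(scope="session")
def two_bench():
    """Two planted sites per protein; primary site scrambled in 25% of them."""
    return e.generate_benchmark(TWO_SITE_SPEC)


@pytest.fixture(scope="session")
def two_model(two_bench):
    return e.train_svm(e.generate_svm_training(two_bench, seed=1), seed=1)


@pytest.fixture(scope="session")
def small_bench():
    return e.generate_benchmark(SMALL_SPEC)


@pytest.fixture(scope="session")
def single_mode_predictions(single_bench, single_model):
    return {
        mode: e.run_mode(
            single_bench.proteins, single_bench.proteins, mode, single_model,
            single_bench.annotations,
        )
        for mode in ("6R", "M6R")
    }


@pytest.fixture(scope="session")
def two_mode_predictions(two_bench, two_model):
    return {
        mode: e.run_mode(
            two_bench.proteins, two_bench.proteins, mode, two_model,
            two_bench.annotations,
        )
        for mode in ("6R", "M6R")
    }


def chain_from(points, aas=None, chain_id="toyA", full_length=None):
    """Helper: build a ProteinChain from raw coordinates."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if aas is None:
        aas = tuple("A" * n)
    return e.ProteinChain(
        id=chain_id,
        seq_numbers=np.arange(1, n + 1),
        aas=tuple(aas),
        coords=points,
        full_sequence_length=full_length,
    )


def uniform_surface(chain, exposed=True):
    area = {int(s): 30.0 if exposed else 0.0 for s in chain.seq_numbers}
    return e.SurfaceAnnotation(chain.id, area)
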