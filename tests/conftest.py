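"""Shared heavy fixtures: one trained planted-motif fixture per session,
with attribution bundles for the test split computed once and reused by the
recovery, faithfulness, and clustering tests."""

import numpy as np
import pytest

from headig.attribution import PathSpec, attribute_all
from headig.model import ClassScoreFn
from headig.synthetic import make_headwise_fixture

FIXTURE_SEED = 0
N_TEST_PROTEINS = 100
IG_STEPS = 64


@pytest.fixture(scope="session")
def trained_fixture():
    fx = make_headwise_fixture(seed=FIXTURE_SEED)
    assert fx.valid, fx.diagnostic
    return fx


@pytest.fixture(scope="session")
def test_bundles(trained_fixture):
    """Attribution bundles (own-class logit) for the test-split proteins."""
    ds = trained_fixture.dataset
    model = trained_fixture.model
    by_id = {r.id: r for r in ds.records}
    bundles = {}
    for pid in ds.test_ids[:N_TEST_PROTEINS]:
        fn = ClassScoreFn(ds.labels[pid], "logit")
        bundles[pid] = attribute_all(model, by_id[pid].residues, fn,
                                     PathSpec(steps=IG_STEPS), sequence_id=pid)
    return bundles


@pytest.fixture(scope="session")
def test_annotation_vectors(trained_fixture, test_bundles):
    ds = trained_fixture.dataset
    return {pid: ds.track_of(pid).to_binary() for pid in test_bundles}
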