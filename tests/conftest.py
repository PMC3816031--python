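"""Shared fixtures: a tiny synthetic speaker every module can train on.

Session-scoped so the corpus is synthesized once; tests must not mutate
the fixture objects (training functions return copies).
"""

from __future__ import annotations

import numpy as np
import pytest

import phonotop as pt


@pytest.fixture(scope="session")
def tiny_spec() -> pt.TruthSpec:
    return pt.TruthSpec(
        n_phones=6, feature_dim=3, state_range=(3, 4), separation=2.0
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec):
    model_set, table = pt.make_truth_models(tiny_spec, seed=101)
    return model_set, table


@pytest.fixture(scope="session")
def tiny_lexicon(tiny_spec):
    return pt.build_toy_lexicon(tiny_spec.inventory(), n_nouns=4, n_verbs=2, seed=101)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_truth, tiny_lexicon, tiny_spec):
    lexicon, grammar = tiny_lexicon
    corpus = pt.synthesize_sentences(
        tiny_truth[0], lexicon, grammar, 24, seed=102
    )
    return pt.make_splits(
        corpus, (0.5, 0.25, 0.25), seed=103, inventory=tiny_spec.inventory()
    )


@pytest.fixture(scope="session")
def trained_models(tiny_corpus, tiny_spec):
    assignment = pt.uniform_assignment(tiny_spec.inventory(), pt.BAKIS1, 3)
    return pt.train_recognizer(
        assignment,
        2,
        tiny_corpus.subset("train"),
        tiny_spec.feature_dim,
        pt.TrainConfig(em_iters=5, split_em_iters=2),
    )


def random_phone_hmm(
    label: str,
    topo: int,
    n_states: int,
    dim: int,
    rng: np.random.Generator,
    n_components: int = 1,
) -> pt.PhoneHMM:
    """A valid random PhoneHMM for oracle comparisons."""
    spec = pt.TopologySpec(topo, n_states)
    mask = pt.build_transition_mask(spec)
    trans = np.zeros(mask.shape)
    for i in range(n_states + 1):
        row = rng.random(mask.shape[1]) * mask[i]
        trans[i] = row / row.sum()
    emissions = [
        pt.GaussianMixtureEmission(
            weights=rng.dirichlet(np.full(n_components, 3.0)),
            means=rng.normal(0, 2, size=(n_components, dim)),
            variances=rng.uniform(0.5, 2.0, size=(n_components, dim)),
        )
        for _ in range(n_states)
    ]
    return pt.PhoneHMM(label, spec, trans, emissions)
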