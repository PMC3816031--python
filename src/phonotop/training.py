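"""End-to-end recognizer training: flat start, embedded EM, mixture growth.

This is the pipeline a fitness evaluation runs for one topology
assignment: build the phone models, flat-start them on the training data,
re-estimate with embedded Baum-Welch, then grow the Gaussian mixtures to
the requested component count in binary stages with a short re-estimation
after each split (mirroring the usual HTK "mixing up" recipe).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import Corpus
from .hmm import (
    ModelSet,
    build_model_set,
    embedded_reestimate,
    flat_start,
    split_mixtures,
)
from .topology import TopologySpec


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the supervised training schedule.

    ``em_iters``: embedded Baum-Welch iterations after flat start (early
    stop when the per-frame log-likelihood gain drops below
    ``tol_per_frame``).  ``split_em_iters``: iterations after each mixture
    doubling.
    """

    em_iters: int = 20
    split_em_iters: int = 5
    tol_per_frame: float = 1e-4


def train_recognizer(
    assignment: dict[str, TopologySpec],
    n_mixtures: int,
    train: Corpus,
    feature_dim: int,
    config: TrainConfig = TrainConfig(),
) -> ModelSet:
    """Train a full phone-HMM bank for one topology assignment."""
    model_set = build_model_set(assignment, feature_dim, n_components=1)
    model_set = flat_start(model_set, train)
    model_set, _ = embedded_reestimate(
        model_set, train, n_iter=config.em_iters, tol_per_frame=config.tol_per_frame
    )
    m = 1
    while m < n_mixtures:
        m = min(2 * m, n_mixtures)
        model_set = split_mixtures(model_set, m)
        model_set, _ = embedded_reestimate(
            model_set,
            train,
            n_iter=config.split_em_iters,
            tol_per_frame=config.tol_per_frame,
        )
    return model_set


def uniform_assignment(
    inventory: list[str], topo_type: int, n_states: int
) -> dict[str, TopologySpec]:
    """Same topology and state count for every phoneme (baseline systems)."""
    spec = TopologySpec(topo_type, n_states)
    return {p: spec for p in inventory}
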