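"""HMM topology specifications and transition masks.

Three phone-HMM topologies are supported, identified by integer codes that
double as gene values in the optimizer's chromosome:

* ``0`` — **Bakis-1**: strict left-to-right; each emitting state has a
  self-loop and an advance-by-one arc.
* ``1`` — **Bakis-2**: Bakis-1 plus skip-by-two arcs (state *i* → *i + 2*),
  the usual "additional transitions" augmentation of a left-to-right HMM.
* ``2`` — **Ergodic**: every emitting state reachable from every other.

All masks use the HTK-style layout with a non-emitting entry state (row 0),
``n`` emitting states (rows 1..n) and a non-emitting exit state (row n+1),
so phone models concatenate directly into sentence-level models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BAKIS1 = 0
BAKIS2 = 1
ERGODIC = 2

TOPOLOGY_NAMES = {BAKIS1: "Bakis-1", BAKIS2: "Bakis-2", ERGODIC: "Ergodic"}

#: Inclusive range of emitting-state counts considered by the optimizer.
MIN_STATES = 3
MAX_STATES = 11


@dataclass(frozen=True)
class TopologySpec:
    """Architecture of one phone HMM: topology type and emitting-state count."""

    topo_type: int
    n_states: int

    def __post_init__(self) -> None:
        if self.topo_type not in TOPOLOGY_NAMES:
            raise ValueError(
                f"unknown topology code {self.topo_type!r}; expected one of "
                f"{sorted(TOPOLOGY_NAMES)}"
            )
        if not (MIN_STATES <= self.n_states <= MAX_STATES):
            raise ValueError(
                f"n_states={self.n_states} outside [{MIN_STATES}, {MAX_STATES}]"
            )

    @property
    def name(self) -> str:
        return TOPOLOGY_NAMES[self.topo_type]


def build_transition_mask(spec: TopologySpec) -> np.ndarray:
    """Boolean (n+2)×(n+2) matrix of permitted arcs for ``spec``.

    Row/column 0 is the non-emitting entry state, rows/columns 1..n the
    emitting states and row/column n+1 the non-emitting exit state.  Entry
    connects to the first emitting state for Bakis topologies and to all
    emitting states for the Ergodic one; exit is reached from the last
    emitting state (Bakis) or from every emitting state (Ergodic).
    """
    n = spec.n_states
    size = n + 2
    mask = np.zeros((size, size), dtype=bool)
    emit = np.arange(1, n + 1)

    if spec.topo_type in (BAKIS1, BAKIS2):
        mask[0, 1] = True                       # entry -> first state
        mask[emit, emit] = True                 # self-loops
        mask[emit[:-1], emit[:-1] + 1] = True   # advance by one
        if spec.topo_type == BAKIS2:
            mask[emit[:-2], emit[:-2] + 2] = True  # skip by two
        mask[n, n + 1] = True                   # last state -> exit
    else:  # ERGODIC
        mask[0, emit] = True
        mask[np.ix_(emit, emit)] = True
        mask[emit, n + 1] = True
    return mask


def emitting_arc_count(spec: TopologySpec) -> int:
    """Number of permitted emitting-to-emitting arcs (excludes entry/exit)."""
    mask = build_transition_mask(spec)
    n = spec.n_states
    return int(mask[1 : n + 1, 1 : n + 1].sum())
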