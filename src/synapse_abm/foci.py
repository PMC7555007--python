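"""F-actin foci: a per-node automaton on a third lattice, plus its feedback field.

TCR–pMHC complexes nucleate F-actin; colocalized or nearby LFA-1–ICAM-1
complexes promote the nucleated state toward polymerization; every non-empty
state self-inhibits.  Connected clusters of polymerization nodes are the
model's F-actin foci.  Formed foci feed back on TCR–pMHC association through
the binding coefficient B (>1 positive, <1 negative feedback).

The automaton draws from its own RNG substream, so with B = 1 the molecular
trajectory is bit-identical to a run without foci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels
from .config import FociParams
from .kinetics import _scratch, foci_neighborhood_offsets
from .lattice_core import SimulationState

FOCI_STATE_NAMES = ("empty", "nucleation", "nucleation_polymerized", "polymerization")
FOCI_EMPTY, FOCI_NUCL, FOCI_NUCL_POLY, FOCI_POLY = range(4)

#: 4-connectivity structuring element for focus cluster labeling
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def update_foci(state: SimulationState, params: FociParams | None = None) -> SimulationState:
    """One synchronous automaton update driven by current complex occupancy."""
    p = state.config.foci if params is None else params
    sc = _scratch(state)
    nb_dx, nb_dy = foci_neighborhood_offsets(state)
    _kernels.foci_phase(
        state.grid_t,
        state.species,
        state.partner,
        state.active,
        state.foci_state,
        state.foci_age,
        sc["snap"],
        state.rng_foci,
        p.p_nucleate,
        p.p_nuc_polymerize,
        p.p_polymerize,
        p.p_decay,
        nb_dx,
        nb_dy,
    )
    return state


def feedback_field(foci_state: np.ndarray, params: FociParams) -> np.ndarray:
    """Per-node multiplier on the TCR–pMHC association probability.

    B at every node carrying a formed focus (polymerization state; optionally
    any non-empty state), 1 elsewhere.  An empty foci lattice therefore
    reproduces the no-feedback model exactly.
    """
    field = np.ones(foci_state.shape, dtype=np.float64)
    if params.feedback_states == "all":
        field[foci_state != FOCI_EMPTY] = params.b
    else:
        field[foci_state == FOCI_POLY] = params.b
    return field


@dataclass(frozen=True)
class FociSummary:
    n_nucleation: int
    n_nucleation_polymerized: int
    n_polymerization: int
    n_clusters: int  # 4-connected clusters of polymerization nodes = formed foci


def foci_summary(foci_state: np.ndarray) -> FociSummary:
    """Per-state node counts and the number of formed foci."""
    poly = foci_state == FOCI_POLY
    _, n_clusters = ndimage.label(poly, structure=_STRUCTURE_4)
    return FociSummary(
        n_nucleation=int((foci_state == FOCI_NUCL).sum()),
        n_nucleation_polymerized=int((foci_state == FOCI_NUCL_POLY).sum()),
        n_polymerization=int(poly.sum()),
        n_clusters=int(n_clusters),
    )
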