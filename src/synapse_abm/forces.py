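"""Deterministic movement biases: size-based segregation and centripetal flow.

Both forces act by reweighting the candidate moves (stay + the four
neighbors) of bound complexes, never by deterministic displacement, so all
motion stays within the kinetic Monte Carlo scheme and the one-agent-per-node
exclusion is preserved.  Free molecules are unbiased.

These functions are the per-unit reference implementation of the weight
algebra used inside the compiled kernels; `move_weights` reproduces the
kernel's final move distribution exactly and is cross-checked against it in
the test suite.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import ForceParams
from .kinetics import KineticsParams, _params
from .lattice_core import SimulationState

logger = logging.getLogger(__name__)

#: candidate order: stay, +x, −x, +y, −y
_DIRS = np.array([[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)


def _unit_pair_class(state: SimulationState, agent_id: int) -> int:
    sp = int(state.species[agent_id])
    if state.partner[agent_id] < 0:
        raise ValueError("force biases apply to bound complexes only")
    return 0 if sp in (0, 1) else 1


def _bias_from_vector(fx: float, fy: float, strength: float) -> np.ndarray:
    """Candidate weights [stay, 4 dirs] from a (possibly zero) bias vector."""
    w = np.ones(5)
    norm = float(np.hypot(fx, fy))
    if norm > 1e-12 and strength > 0.0:
        ux, uy = fx / norm, fy / norm
        for d in range(1, 5):
            w[d] = max(0.0, 1.0 + strength * (_DIRS[d, 0] * ux + _DIRS[d, 1] * uy))
    return w / w.sum()


def net_sbs_vector(state: SimulationState, agent_id: int, params: ForceParams) -> tuple[float, float]:
    """Sum of weighted unit vectors pointing away from every opposite-size-class
    complex within R_force of the unit (direct pairwise evaluation)."""
    lat = state.config.lattice
    pair = _unit_pair_class(state, agent_id)
    other_rep = 2 if pair == 0 else 0  # T-side representative species code
    x0, y0 = int(state.xs[agent_id]), int(state.ys[agent_id])
    r_nodes = params.r_force_um / lat.node_spacing_um
    fx = fy = 0.0
    reps = np.flatnonzero((state.species == other_rep) & (state.partner >= 0))
    for j in reps:
        dx = x0 - int(state.xs[j])
        dy = y0 - int(state.ys[j])
        dist = np.hypot(dx, dy)
        if 0 < dist <= r_nodes:
            w = 1.0 / dist if params.sbs_kernel == "inverse_r" else 1.0
            fx += w * dx / dist
            fy += w * dy / dist
    return fx, fy


def sbs_bias(state: SimulationState, agent_id: int, params: ForceParams | None = None) -> np.ndarray:
    """Normalized candidate weights from size-based segregation repulsion."""
    params = state.config.forces if params is None else params
    if params.sbs_strength <= 0.0:
        return np.full(5, 0.2)
    fx, fy = net_sbs_vector(state, agent_id, params)
    return _bias_from_vector(fx, fy, params.sbs_strength)


def centripetal_bias(
    state: SimulationState, agent_id: int, params: ForceParams | None = None
) -> np.ndarray:
    """Normalized candidate weights favoring the move toward the synapse center.

    Uniform when coupling is disabled or the unit sits exactly at the center.
    """
    params = state.config.forces if params is None else params
    pair = _unit_pair_class(state, agent_id)
    strength = params.centripetal_strength if pair == 0 else params.centripetal_strength_long
    if not params.coupling_enabled or strength <= 0.0:
        return np.full(5, 0.2)
    c = state.config.lattice.center
    fx = c - float(state.xs[agent_id])
    fy = c - float(state.ys[agent_id])
    return _bias_from_vector(fx, fy, strength)


def combine_biases(*weight_vectors: np.ndarray) -> np.ndarray:
    """Elementwise product of candidate-weight vectors, renormalized.

    Falls back to a certain "stay" (with a logged warning) if the product is
    identically zero.
    """
    out = np.ones(5)
    for w in weight_vectors:
        w = np.asarray(w, dtype=float)
        if w.shape != (5,):
            raise ValueError("weight vectors must have 5 candidates (stay + 4 neighbors)")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        out *= w
    total = out.sum()
    if total <= 0.0:
        logger.warning("all-zero combined move weights; unit stays put")
        out = np.zeros(5)
        out[0] = 1.0
        return out
    return out / total


def diffusion_weights(p_move: float) -> np.ndarray:
    """Unbiased candidate weights: stay with 1−p, each neighbor with p/4."""
    return np.array([1.0 - p_move, 0.25 * p_move, 0.25 * p_move, 0.25 * p_move, 0.25 * p_move])


def move_weights(
    state: SimulationState, agent_id: int, params: KineticsParams | None = None
) -> np.ndarray:
    """Final move distribution of a bound complex, as sampled by the kernel.

    Mirrors the kernel exactly: the SBS direction is read from the scatter
    field (refreshed here), so call sites see the same distribution the
    compiled move phase samples from — before occupancy rejection.
    """
    from .kinetics import refresh_sbs_fields

    p = _params(state, params)
    f = state.config.forces
    pair = _unit_pair_class(state, agent_id)
    diff = diffusion_weights(float(p.p_move_pair[pair]))
    cent = centripetal_bias(state, agent_id, f)
    if f.sbs_strength > 0.0:
        refresh_sbs_fields(state)
        sc = state._sbs_fields
        x, y = int(state.xs[agent_id]), int(state.ys[agent_id])
        fx = sc["fields"][2 * pair, y, x]
        fy = sc["fields"][2 * pair + 1, y, x]
        sbs = _bias_from_vector(fx, fy, f.sbs_strength)
    else:
        sbs = np.full(5, 0.2)
    return combine_biases(diff, sbs, cent)
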