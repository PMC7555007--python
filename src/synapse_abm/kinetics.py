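"""Per-timestep stochastic dynamics: diffusion, binding, unbinding.

The module exposes the individual sub-steps (`step_diffusion`,
`attempt_unbinding`, `attempt_binding`) for inspection and testing, the
composed `simulation_step`, and a fused `run` driver for long simulations.
All of them execute the same compiled kernels, so the step-wise and fused
paths produce identical trajectories for identical seeds.

Within one step the update order is: force-biased movement → unbinding →
binding → foci update.  A molecule freed by unbinding is therefore eligible
to rebind in the same step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import PAIR_NAMES, SPECIES_NAMES, SimulationConfig
from .lattice_core import SimulationState

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KineticsParams:
    """Per-step probabilities derived from a :class:`SimulationConfig`.

    ``p_on_raw`` is B_global·τ/τ_on *before* clamping; the kernels clamp to 1
    after applying any foci feedback multiplier.  A warning is emitted if the
    unclamped value already exceeds 1 (the timestep is too coarse for the
    chosen kon/V).
    """

    p_move_sp: np.ndarray  # float64[4], per species code
    p_move_pair: np.ndarray  # float64[2], per complex class
    p_on_raw: np.ndarray  # float64[2]
    p_off: np.ndarray  # float64[2]

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "KineticsParams":
        lat = config.lattice
        p_move_sp = np.zeros(4)
        for sp in config.species:
            p_move_sp[sp.code] = sp.move_probability(lat)
        p_move_pair = np.zeros(2)
        for k, pair in enumerate(PAIR_NAMES):
            d = config.complex_diffusion(pair)
            p_move_pair[k] = 4.0 * d * lat.timestep_s / lat.node_spacing_um**2
            if p_move_pair[k] > 1.0:
                raise ValueError(f"complex {pair}: move probability exceeds 1")
        p_on_raw = np.zeros(2)
        p_off = np.zeros(2)
        for rule in config.rules:
            k = rule.pair_index
            tau_on = rule.tau_on_s(lat)
            p_on_raw[k] = (
                0.0 if np.isinf(tau_on) else config.binding_scale * lat.timestep_s / tau_on
            )
            p_off[k] = rule.p_off(lat)
            if p_on_raw[k] > 1.0:
                warnings.warn(
                    f"{rule.pair}: p_on = {p_on_raw[k]:.3g} clamped to 1; "
                    "timestep too large for this kon/V",
                    stacklevel=2,
                )
        return cls(p_move_sp, p_move_pair, p_on_raw, p_off)


def _scratch(state: SimulationState) -> dict:
    sc = state._sbs_fields
    if sc is None:
        n = state.config.lattice.nodes_per_side
        cap = max(state.n_agents, 1)
        sc = {
            "fields": np.zeros((4, n, n), dtype=np.float64),
            "unit_agents": np.empty(cap, dtype=np.int32),
            "unit_kinds": np.empty(cap, dtype=np.int8),
            "snap": np.empty((n, n), dtype=np.int8),
            "params": None,
            "sbs_kernel": None,
            "nb_offsets": None,
        }
        state._sbs_fields = sc
    if sc["unit_agents"].shape[0] < state.n_agents:  # fixture helpers may grow the table
        sc["unit_agents"] = np.empty(state.n_agents, dtype=np.int32)
        sc["unit_kinds"] = np.empty(state.n_agents, dtype=np.int8)
    return sc


def _params(state: SimulationState, params: KineticsParams | None) -> KineticsParams:
    if params is not None:
        return params
    sc = _scratch(state)
    if sc["params"] is None:
        sc["params"] = KineticsParams.from_config(state.config)
    return sc["params"]


def _disk_offsets(radius_um: float, spacing_um: float, include_center: bool):
    """Integer offsets within a Euclidean radius, with unit vectors away from 0."""
    r_nodes = radius_um / spacing_um
    m = int(np.floor(r_nodes))
    dys, dxs = np.mgrid[-m : m + 1, -m : m + 1]
    dist = np.hypot(dxs, dys)
    mask = dist <= r_nodes
    if not include_center:
        mask &= dist > 0
    return dxs[mask].astype(np.int64), dys[mask].astype(np.int64), dist[mask]


def sbs_kernel_offsets(state: SimulationState):
    """Precomputed SBS scatter kernel (offsets + weighted unit vectors)."""
    sc = _scratch(state)
    if sc["sbs_kernel"] is None:
        f = state.config.forces
        lat = state.config.lattice
        kdx, kdy, dist = _disk_offsets(f.r_force_um, lat.node_spacing_um, include_center=False)
        if dist.size:
            w = 1.0 / dist if f.sbs_kernel == "inverse_r" else np.ones_like(dist)
            kwx = w * kdx / dist
            kwy = w * kdy / dist
        else:
            kwx = np.zeros(0)
            kwy = np.zeros(0)
        sc["sbs_kernel"] = (kdx, kdy, kwx, kwy)
    return sc["sbs_kernel"]


def foci_neighborhood_offsets(state: SimulationState):
    sc = _scratch(state)
    if sc["nb_offsets"] is None:
        lat = state.config.lattice
        nb_dx, nb_dy, _ = _disk_offsets(
            state.config.foci.r_neighborhood_um, lat.node_spacing_um, include_center=True
        )
        sc["nb_offsets"] = (nb_dx, nb_dy)
    return sc["nb_offsets"]


def refresh_sbs_fields(state: SimulationState) -> None:
    """Recompute the SBS repulsion fields from current complex positions."""
    sc = _scratch(state)
    kdx, kdy, kwx, kwy = sbs_kernel_offsets(state)
    _kernels.compute_sbs_fields(
        state.grid_t, state.species, state.xs, state.ys, state.partner, sc["fields"], kdx, kdy, kwx, kwy
    )


def step_diffusion(state: SimulationState, params: KineticsParams | None = None) -> SimulationState:
    """One movement sub-step (random walk + forces); advances the clock by τ."""
    p = _params(state, params)
    sc = _scratch(state)
    f = state.config.forces
    if f.sbs_strength > 0.0:
        refresh_sbs_fields(state)
    _kernels.move_phase(
        state.grid_t,
        state.grid_a,
        state.active,
        state.species,
        state.xs,
        state.ys,
        state.partner,
        state.rng,
        p.p_move_sp,
        p.p_move_pair,
        f.coupling_enabled,
        f.centripetal_strength,
        f.centripetal_strength_long,
        f.sbs_strength,
        sc["fields"],
        state.config.lattice.center,
        sc["unit_agents"],
        sc["unit_kinds"],
    )
    state.step_count += 1
    return state


def attempt_unbinding(state: SimulationState, params: KineticsParams | None = None) -> SimulationState:
    """Dissociate each bound pair with probability 1 − exp(−koff·τ)."""
    p = _params(state, params)
    _kernels.unbind_phase(state.species, state.partner, state.rng, p.p_off)
    return state


def attempt_binding(
    state: SimulationState,
    params: KineticsParams | None = None,
    b_field_override: float | None = None,
) -> SimulationState:
    """Form complexes at nodes where free receptor and ligand are colocalized.

    The foci feedback field (binding coefficient B at focus nodes, 1
    elsewhere) modulates the TCR–pMHC rule only.  ``b_field_override``
    replaces the configured B (testing hook).
    """
    p = _params(state, params)
    foci = state.config.foci
    b = foci.b if b_field_override is None else b_field_override
    _kernels.bind_phase(
        state.grid_a,
        state.species,
        state.xs,
        state.ys,
        state.partner,
        state.rng,
        p.p_on_raw,
        foci.enabled,
        state.foci_state,
        b,
        foci.feedback_states == "all",
    )
    return state


def simulation_step(state: SimulationState, params: KineticsParams | None = None) -> SimulationState:
    """One full timestep: movement → unbinding → binding → foci; clock += τ."""
    return run(state, n_steps=1, params=params)


def run_checked(
    state: SimulationState,
    duration_s: float | None = None,
    n_steps: int | None = None,
    params: KineticsParams | None = None,
    check_every: int = 1,
) -> SimulationState:
    """Advance the simulation, validating state invariants as it goes.

    After every ``check_every`` steps the full exclusion / grid-table /
    pair-consistency invariant set is asserted inside the compiled kernel,
    and species conservation is asserted against the initial composition.
    Raises ``AssertionError`` naming the violated invariant.
    """
    if (duration_s is None) == (n_steps is None):
        raise ValueError("specify exactly one of duration_s or n_steps")
    if n_steps is None:
        n_steps = int(round(duration_s / state.config.lattice.timestep_s))
    codes = {
        1: "grid/table mismatch",
        2: "agent on blocked node",
        3: "wrong-side agent on grid",
        4: "occupancy count mismatch",
        5: "non-mutual partner",
        6: "bound pair not colocalized",
        7: "invalid species pairing",
    }
    species_totals = np.bincount(state.species, minlength=4).copy()
    done = 0
    while done < n_steps:
        chunk = min(check_every, n_steps - done)
        run(state, n_steps=chunk, params=params)
        code = _kernels.validate_state(
            state.grid_t, state.grid_a, state.active, state.species, state.xs, state.ys, state.partner
        )
        assert code == 0, f"invariant violated at step {state.step_count}: {codes[code]}"
        now = np.bincount(state.species, minlength=4)
        assert (now == species_totals).all(), f"species conservation violated at {state.step_count}"
        done += chunk
    return state


def run(
    state: SimulationState,
    duration_s: float | None = None,
    n_steps: int | None = None,
    params: KineticsParams | None = None,
) -> SimulationState:
    """Advance the simulation with the fused kernel driver."""
    if (duration_s is None) == (n_steps is None):
        raise ValueError("specify exactly one of duration_s or n_steps")
    if n_steps is None:
        n_steps = int(round(duration_s / state.config.lattice.timestep_s))
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        return state
    p = _params(state, params)
    sc = _scratch(state)
    f = state.config.forces
    foci = state.config.foci
    kdx, kdy, kwx, kwy = sbs_kernel_offsets(state)
    nb_dx, nb_dy = foci_neighborhood_offsets(state)
    state.step_count = _kernels.run_steps(
        n_steps,
        state.step_count,
        state.grid_t,
        state.grid_a,
        state.active,
        state.species,
        state.xs,
        state.ys,
        state.partner,
        state.foci_state,
        state.foci_age,
        state.rng,
        state.rng_foci,
        p.p_move_sp,
        p.p_move_pair,
        p.p_on_raw,
        p.p_off,
        f.coupling_enabled,
        f.centripetal_strength,
        f.centripetal_strength_long,
        f.sbs_strength,
        sc["fields"],
        kdx,
        kdy,
        kwx,
        kwy,
        f.sbs_update_interval,
        state.config.lattice.center,
        foci.enabled,
        foci.b,
        foci.feedback_states == "all",
        foci.p_nucleate,
        foci.p_nuc_polymerize,
        foci.p_polymerize,
        foci.p_decay,
        nb_dx,
        nb_dy,
        sc["unit_agents"],
        sc["unit_kinds"],
        sc["snap"],
    )
    return state
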