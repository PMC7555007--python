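"""Paired membrane lattices: state container, construction, geometry helpers.

The world is two square lattices sharing one coordinate system — the T-cell
membrane (TCR, LFA-1) and the bilayer/APC membrane (pMHC, ICAM-1) — plus the
F-actin foci lattice.  Each node of a molecular lattice holds at most one
agent.  A bound receptor–ligand pair occupies the *same* node index on the
two lattices and moves as one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import make_stream
from .config import (
    APC_SIDE,
    SPECIES_NAMES,
    ConfigError,
    LatticeConfig,
    SimulationConfig,
    SpeciesSpec,
    T_CELL_SIDE,
)

EMPTY = -1

#: integer codes used in snapshot exports (0 empty is implicit)
SNAPSHOT_CODES = {
    "empty": 0,
    "TCR": 1,
    "pMHC": 2,
    "LFA1": 3,
    "ICAM1": 4,
    "TCR:pMHC": 5,  # bound agent, written on both lattices
    "LFA1:ICAM1": 6,
}

_T_SIDE_CODES = (0, 2)  # TCR, LFA1
_APC_SIDE_CODES = (1, 3)  # pMHC, ICAM1


class DomainError(ValueError):
    """A node index outside the active circular domain."""


class CapacityError(ValueError):
    """Requested density exceeds the lattice capacity."""


def active_mask(config: LatticeConfig) -> np.ndarray:
    """Boolean (n, n) mask of nodes inside the circular synapse domain."""
    n = config.nodes_per_side
    c = config.center
    r_nodes = config.synapse_radius_um / config.node_spacing_um
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= r_nodes**2


@dataclass
class SimulationState:
    """Full mutable simulation world.

    Agent table layout: ``species[i]`` is the integer species code, ``xs/ys``
    the node coordinates, and ``partner[i]`` the agent id of the binding
    partner (−1 when free).  ``grid_t``/``grid_a`` map nodes to agent ids.
    Two independent RNG substreams are kept: ``rng`` drives molecular
    kinetics and movement, ``rng_foci`` drives the foci automaton, so foci
    bookkeeping never perturbs the molecular trajectory.
    """

    config: SimulationConfig
    grid_t: np.ndarray  # int32 (n, n)
    grid_a: np.ndarray  # int32 (n, n)
    active: np.ndarray  # uint8 (n, n)
    species: np.ndarray  # int8 (N,)
    xs: np.ndarray  # int32 (N,)
    ys: np.ndarray  # int32 (N,)
    partner: np.ndarray  # int32 (N,)
    foci_state: np.ndarray  # int8 (n, n)
    foci_age: np.ndarray  # int32 (n, n)
    rng: np.ndarray  # uint64 (1,)
    rng_foci: np.ndarray  # uint64 (1,)
    step_count: int = 0
    # scratch buffers and cached derived parameters (not part of the logical state)
    _sbs_fields: dict | None = field(default=None, repr=False, compare=False)

    @property
    def clock_s(self) -> float:
        return self.step_count * self.config.lattice.timestep_s

    @property
    def n_agents(self) -> int:
        return self.species.shape[0]

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-species free/bound/total agent counts."""
        out: dict[str, dict[str, int]] = {}
        for code, name in enumerate(SPECIES_NAMES):
            mask = self.species == code
            bound = int(np.count_nonzero(mask & (self.partner >= 0)))
            total = int(np.count_nonzero(mask))
            out[name] = {"free": total - bound, "bound": bound, "total": total}
        return out

    def copy(self) -> "SimulationState":
        return SimulationState(
            config=self.config,
            grid_t=self.grid_t.copy(),
            grid_a=self.grid_a.copy(),
            active=self.active,
            species=self.species.copy(),
            xs=self.xs.copy(),
            ys=self.ys.copy(),
            partner=self.partner.copy(),
            foci_state=self.foci_state.copy(),
            foci_age=self.foci_age.copy(),
            rng=self.rng.copy(),
            rng_foci=self.rng_foci.copy(),
            step_count=self.step_count,
        )


def realized_count(density_per_um2: float, config: LatticeConfig) -> int:
    """Number of agents placed for a target density over the active disk."""
    return int(np.rint(density_per_um2 * config.active_area_um2))


def build_initial_state(
    config: SimulationConfig, seed: int, species: tuple[SpeciesSpec, ...] | None = None
) -> SimulationState:
    """Seed both lattices with uniformly placed free agents.

    Placement draws from ``numpy.random.default_rng(seed)``; the kernel RNG
    substreams are derived from the same seed.  Identical (config, seed)
    therefore yields a byte-identical state.
    """
    species = config.species if species is None else species
    lat = config.lattice
    n = lat.nodes_per_side
    mask = active_mask(lat)
    n_active = int(mask.sum())

    counts = [(sp, realized_count(sp.density_per_um2, lat)) for sp in species]
    for side, side_name in ((T_CELL_SIDE, "T-cell"), (APC_SIDE, "APC")):
        need = sum(c for sp, c in counts if sp.side == side)
        if need > n_active:
            names = [sp.name for sp, _ in counts if sp.side == side]
            raise CapacityError(
                f"{side_name} lattice: {need} agents requested for species {names} "
                f"but only {n_active} active nodes are available"
            )

    total = sum(c for _, c in counts)
    grid_t = np.full((n, n), EMPTY, dtype=np.int32)
    grid_a = np.full((n, n), EMPTY, dtype=np.int32)
    sp_arr = np.empty(total, dtype=np.int8)
    xs = np.empty(total, dtype=np.int32)
    ys = np.empty(total, dtype=np.int32)
    partner = np.full(total, EMPTY, dtype=np.int32)

    placement = np.random.default_rng(seed)
    active_nodes = np.flatnonzero(mask.ravel())
    free_nodes = {T_CELL_SIDE: active_nodes.copy(), APC_SIDE: active_nodes.copy()}
    grids = {T_CELL_SIDE: grid_t, APC_SIDE: grid_a}

    i = 0
    for sp, count in counts:  # canonical order = config order
        if count == 0:
            continue
        pool = free_nodes[sp.side]
        chosen_idx = placement.choice(pool.size, size=count, replace=False)
        chosen = pool[chosen_idx]
        free_nodes[sp.side] = np.delete(pool, chosen_idx)
        cy, cx = np.divmod(chosen, n)
        ids = np.arange(i, i + count, dtype=np.int32)
        grids[sp.side][cy, cx] = ids
        sp_arr[i : i + count] = sp.code
        xs[i : i + count] = cx
        ys[i : i + count] = cy
        i += count

    return SimulationState(
        config=config,
        grid_t=grid_t,
        grid_a=grid_a,
        active=mask.astype(np.uint8),
        species=sp_arr,
        xs=xs,
        ys=ys,
        partner=partner,
        foci_state=np.zeros((n, n), dtype=np.int8),
        foci_age=np.zeros((n, n), dtype=np.int32),
        rng=make_stream(seed, stream=1),
        rng_foci=make_stream(seed, stream=2),
    )


# -- geometry -----------------------------------------------------------------


def _in_domain(node: tuple[int, int], config: LatticeConfig) -> bool:
    x, y = node
    n = config.nodes_per_side
    if not (0 <= x < n and 0 <= y < n):
        return False
    c = config.center
    r_nodes = config.synapse_radius_um / config.node_spacing_um
    return (x - c) ** 2 + (y - c) ** 2 <= r_nodes**2


def node_neighbors(node: tuple[int, int], config: LatticeConfig) -> list[tuple[int, int]]:
    """4-neighborhood (von Neumann) of ``node``, clipped to the active disk.

    Order is deterministic: +x, −x, +y, −y.
    """
    if not _in_domain(node, config):
        raise DomainError(f"node {node} is outside the active domain")
    x, y = node
    out = []
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = (x + dx, y + dy)
        if _in_domain(nb, config):
            out.append(nb)
    return out


def distance_um(node_a: tuple[int, int], node_b: tuple[int, int], config: LatticeConfig) -> float:
    """Euclidean distance between node centers, in µm."""
    dx = (node_a[0] - node_b[0]) * config.node_spacing_um
    dy = (node_a[1] - node_b[1]) * config.node_spacing_um
    return float(np.hypot(dx, dy))


# -- fixture helpers ----------------------------------------------------------


def add_agent(state: SimulationState, species_name: str, node: tuple[int, int]) -> int:
    """Append one free agent at ``node`` (test/fixture construction).

    Returns the new agent id.  Raises if the node is occupied on the
    species' lattice or outside the domain.
    """
    if species_name not in SPECIES_NAMES:
        raise ConfigError(f"unknown species {species_name!r}")
    if not _in_domain(node, state.config.lattice):
        raise DomainError(f"node {node} is outside the active domain")
    code = SPECIES_NAMES.index(species_name)
    grid = state.grid_t if code in _T_SIDE_CODES else state.grid_a
    x, y = node
    if grid[y, x] != EMPTY:
        raise CapacityError(f"node {node} already occupied on that lattice")
    i = state.n_agents
    state.species = np.append(state.species, np.int8(code))
    state.xs = np.append(state.xs, np.int32(x))
    state.ys = np.append(state.ys, np.int32(y))
    state.partner = np.append(state.partner, np.int32(EMPTY))
    grid[y, x] = i
    return i


def bind_pair(state: SimulationState, node: tuple[int, int]) -> None:
    """Force-bind the colocalized free receptor/ligand pair at ``node``."""
    x, y = node
    i, j = int(state.grid_t[y, x]), int(state.grid_a[y, x])
    if i < 0 or j < 0:
        raise ConfigError(f"node {node} does not hold a colocalized pair")
    if state.partner[i] >= 0 or state.partner[j] >= 0:
        raise ConfigError(f"agents at node {node} are already bound")
    state.partner[i] = j
    state.partner[j] = i


# -- invariants ---------------------------------------------------------------


def check_invariants(state: SimulationState) -> None:
    """Assert exclusion, grid/table consistency, and pair consistency.

    Intended for exhaustive use on small lattices in tests; O(n² + N).
    """
    for grid, side_codes, label in (
        (state.grid_t, _T_SIDE_CODES, "T"),
        (state.grid_a, _APC_SIDE_CODES, "APC"),
    ):
        occupied = grid >= 0
        assert not (occupied & (state.active == 0)).any(), f"{label}: agent on blocked node"
        ids = grid[occupied]
        assert len(ids) == len(set(ids.tolist())), f"{label}: duplicate agent id on grid"
        for i in ids:
            assert state.species[i] in side_codes, f"{label}: wrong-side agent {i}"
            assert grid[state.ys[i], state.xs[i]] == i, f"{label}: grid/table mismatch for {i}"
    # every agent is on its grid exactly once
    n_on_grids = int((state.grid_t >= 0).sum() + (state.grid_a >= 0).sum())
    assert n_on_grids == state.n_agents, "agent table and grids disagree"
    # bound pairs: mutual partners, correct species pairing, identical node
    for i in np.flatnonzero(state.partner >= 0):
        j = state.partner[i]
        assert state.partner[j] == i, f"partner of {i} is not mutual"
        assert (state.xs[i], state.ys[i]) == (state.xs[j], state.ys[j]), (
            f"bound pair {i},{j} not colocalized"
        )
        pair = tuple(sorted((int(state.species[i]), int(state.species[j]))))
        assert pair in ((0, 1), (2, 3)), f"invalid species pairing {pair}"


# -- snapshot export ----------------------------------------------------------


def snapshot_grid(state: SimulationState, side: str) -> np.ndarray:
    """Integer-coded (n, n) occupancy matrix for one lattice."""
    grid = state.grid_t if side == T_CELL_SIDE else state.grid_a
    out = np.zeros(grid.shape, dtype=np.int8)
    occ = grid >= 0
    ids = grid[occ]
    codes = np.empty(ids.shape, dtype=np.int8)
    for k, i in enumerate(ids):
        sp = int(state.species[i])
        if state.partner[i] >= 0:
            codes[k] = SNAPSHOT_CODES["TCR:pMHC"] if sp in (0, 1) else SNAPSHOT_CODES["LFA1:ICAM1"]
        else:
            codes[k] = sp + 1
    out[occ] = codes
    return out


def write_snapshot(state: SimulationState, path) -> None:
    """Plain-text snapshot of both molecular lattices and the foci lattice.

    One header line documents the integer codes; each lattice is one
    whitespace-separated integer matrix, suitable for diffing in tests.
    """
    legend = " ".join(f"{v}={k}" for k, v in SNAPSHOT_CODES.items())
    with open(path, "w") as fh:
        fh.write(f"# synapse-abm snapshot t={state.clock_s:.2f}s codes: {legend}; "
                 "foci: 0=empty 1=nucleation 2=nucleation_polymerized 3=polymerization\n")
        for label, mat in (
            ("t_cell", snapshot_grid(state, T_CELL_SIDE)),
            ("apc", snapshot_grid(state, APC_SIDE)),
            ("foci", state.foci_state),
        ):
            fh.write(f"# lattice {label}\n")
            np.savetxt(fh, mat, fmt="%d")


def read_snapshot(path) -> dict[str, np.ndarray]:
    """Parse a snapshot file back into named integer matrices."""
    blocks: dict[str, list[list[int]]] = {}
    current: list[list[int]] | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# lattice "):
                current = blocks.setdefault(line.split()[-1], [])
            elif line.startswith("#") or not line.strip():
                continue
            elif current is not None:
                current.append([int(v) for v in line.split()])
    return {k: np.array(v, dtype=np.int8) for k, v in blocks.items()}
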