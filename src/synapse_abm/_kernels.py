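"""Numba kernels for the per-step stochastic dynamics.

One simulation step applies, in order: force-biased movement of all mobile
units (free agents and bound pairs), complex dissociation, complex formation
at colocalized nodes, and the F-actin foci automaton.  The same njit phase
functions back both the step-wise Python API (kinetics/foci modules) and the
fused multi-step driver used by the experiment runner, so there is a single
source of truth for the dynamics.

Conventions: species codes TCR=0, pMHC=1, LFA1=2, ICAM1=3; complex classes
0 = TCR–pMHC (short), 1 = LFA-1–ICAM-1 (long); foci states 0 = empty,
1 = nucleation, 2 = nucleation-polymerized, 3 = polymerization.  The T-side
member (TCR or LFA-1) is the representative of a bound pair.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rng import rand_below, rand_f64

EMPTY = -1
FOCI_EMPTY, FOCI_NUCL, FOCI_NUCL_POLY, FOCI_POLY = 0, 1, 2, 3

# candidate move directions (order: +x, -x, +y, -y; index 0 of the weight
# vector is "stay")
DX = np.array([1, -1, 0, 0], dtype=np.int64)
DY = np.array([0, 0, 1, -1], dtype=np.int64)
DXF = DX.astype(np.float64)
DYF = DY.astype(np.float64)


@njit(cache=True, inline="always")
def _dir_factor(d, use_c, sc, cvx, cvy, use_s, ss, gvx, gvy):
    """Force multiplier for move direction d; non-negative by construction."""
    f = 1.0
    if use_c:
        f *= max(0.0, 1.0 + sc * (DXF[d] * cvx + DYF[d] * cvy))
    if use_s:
        f *= max(0.0, 1.0 + ss * (DXF[d] * gvx + DYF[d] * gvy))
    return f


@njit(cache=True)
def compute_sbs_fields(grid_unused, sp, xs, ys, partner, fields, kdx, kdy, kwx, kwy):
    """Scatter the SBS repulsion field of each complex class.

    ``fields`` is (4, n, n): [0],[1] = x/y force felt by short complexes
    (sourced by long complexes); [2],[3] = force felt by long complexes
    (sourced by short ones).  Kernel offsets carry weighted unit vectors
    pointing away from the source.
    """
    fields[:] = 0.0
    n = fields.shape[1]
    nk = kdx.shape[0]
    for i in range(sp.shape[0]):
        if partner[i] < 0:
            continue
        s = sp[i]
        if s == 0:  # short complex -> repels long ones
            base = 2
        elif s == 2:  # long complex -> repels short ones
            base = 0
        else:
            continue  # APC-side member of the pair; counted via its rep
        x = xs[i]
        y = ys[i]
        for k in range(nk):
            tx = x + kdx[k]
            ty = y + kdy[k]
            if 0 <= tx < n and 0 <= ty < n:
                fields[base, ty, tx] += kwx[k]
                fields[base + 1, ty, tx] += kwy[k]


@njit(cache=True)
def move_phase(
    grid_t,
    grid_a,
    active,
    sp,
    xs,
    ys,
    partner,
    rng,
    p_move_sp,
    p_move_pair,
    coupling_enabled,
    sc_short,
    sc_long,
    ss,
    fields,
    cx,
    unit_agents,
    unit_kinds,
):
    """Random-walk movement with exclusion and force-biased complex motion.

    Units are updated in a fresh random permutation.  A move is rejected if
    any target node is occupied or outside the active disk; bound pairs move
    synchronously on both lattices.
    """
    n = grid_t.shape[0]
    n_agents = sp.shape[0]
    # collect mobile units: free agents + one T-side representative per pair
    n_units = 0
    for i in range(n_agents):
        s = sp[i]
        if s == 0 or s == 2:
            unit_agents[n_units] = i
            unit_kinds[n_units] = (1 if s == 0 else 2) if partner[i] >= 0 else 0
            n_units += 1
        elif partner[i] < 0:
            unit_agents[n_units] = i
            unit_kinds[n_units] = 0
            n_units += 1
    # Fisher-Yates permutation
    for k in range(n_units - 1, 0, -1):
        j = rand_below(rng, k + 1)
        ta, tk = unit_agents[k], unit_kinds[k]
        unit_agents[k], unit_kinds[k] = unit_agents[j], unit_kinds[j]
        unit_agents[j], unit_kinds[j] = ta, tk

    wdir = np.empty(4, dtype=np.float64)
    for u in range(n_units):
        i = unit_agents[u]
        kind = unit_kinds[u]
        x = xs[i]
        y = ys[i]
        if kind == 0:  # free agent: unbiased random walk
            pm = p_move_sp[sp[i]]
            if pm <= 0.0:
                continue
            if rand_f64(rng) >= pm:
                continue
            d = rand_below(rng, 4)
            tx = x + DX[d]
            ty = y + DY[d]
            if tx < 0 or tx >= n or ty < 0 or ty >= n or active[ty, tx] == 0:
                continue
            s = sp[i]
            if s == 0 or s == 2:
                if grid_t[ty, tx] != EMPTY:
                    continue
                grid_t[y, x] = EMPTY
                grid_t[ty, tx] = i
            else:
                if grid_a[ty, tx] != EMPTY:
                    continue
                grid_a[y, x] = EMPTY
                grid_a[ty, tx] = i
            xs[i] = tx
            ys[i] = ty
        else:  # bound complex: biased walk, both lattices move together
            pair = kind - 1
            pm = p_move_pair[pair]
            if pm <= 0.0 and not coupling_enabled:
                continue
            if pm <= 0.0:
                continue
            sc = sc_short if pair == 0 else sc_long
            use_c = coupling_enabled and sc > 0.0
            cvx = 0.0
            cvy = 0.0
            if use_c:
                vx = cx - x
                vy = cx - y
                norm = np.sqrt(vx * vx + vy * vy)
                if norm > 1e-12:
                    cvx = vx / norm
                    cvy = vy / norm
                else:
                    use_c = False
            gvx = 0.0
            gvy = 0.0
            use_s = ss > 0.0
            if use_s:
                fx = fields[2 * pair, y, x]
                fy = fields[2 * pair + 1, y, x]
                gn = np.sqrt(fx * fx + fy * fy)
                if gn > 1e-12:
                    gvx = fx / gn
                    gvy = fy / gn
                else:
                    use_s = False
            w0 = 1.0 - pm
            base = 0.25 * pm
            wsum = w0
            for d in range(4):
                wd = base * _dir_factor(d, use_c, sc, cvx, cvy, use_s, ss, gvx, gvy)
                wdir[d] = wd
                wsum += wd
            if wsum <= 0.0:
                continue  # degenerate all-zero weights: stay put
            r = rand_f64(rng) * wsum
            if r < w0:
                continue
            r -= w0
            d = 3
            for dd in range(4):
                if r < wdir[dd]:
                    d = dd
                    break
                r -= wdir[dd]
            tx = x + DX[d]
            ty = y + DY[d]
            if tx < 0 or tx >= n or ty < 0 or ty >= n or active[ty, tx] == 0:
                continue
            if grid_t[ty, tx] != EMPTY or grid_a[ty, tx] != EMPTY:
                continue
            j = partner[i]
            grid_t[y, x] = EMPTY
            grid_a[y, x] = EMPTY
            grid_t[ty, tx] = i
            grid_a[ty, tx] = j
            xs[i] = tx
            ys[i] = ty
            xs[j] = tx
            ys[j] = ty


@njit(cache=True)
def unbind_phase(sp, partner, rng, p_off):
    """Each bound pair dissociates with p_off = 1 − exp(−koff·τ)."""
    for i in range(sp.shape[0]):
        s = sp[i]
        if (s == 0 or s == 2) and partner[i] >= 0:
            po = p_off[0] if s == 0 else p_off[1]
            if po > 0.0 and rand_f64(rng) < po:
                j = partner[i]
                partner[i] = EMPTY
                partner[j] = EMPTY


@njit(cache=True)
def bind_phase(
    grid_a, sp, xs, ys, partner, rng, p_on_raw, foci_enabled, foci_state, b_coeff, feedback_all
):
    """Colocalized free receptor/ligand pairs bind with p_on = clamp(B·τ/τ_on).

    ``p_on_raw`` is the unclamped global-scale association probability; the
    foci feedback multiplier (the binding coefficient B at focus-bearing
    nodes) applies to the TCR–pMHC rule only, before clamping.
    """
    for i in range(sp.shape[0]):
        if partner[i] >= 0:
            continue
        s = sp[i]
        if s == 0:
            j = grid_a[ys[i], xs[i]]
            if j >= 0 and sp[j] == 1 and partner[j] < 0:
                p = p_on_raw[0]
                if foci_enabled:
                    fs = foci_state[ys[i], xs[i]]
                    if fs == FOCI_POLY or (feedback_all and fs != FOCI_EMPTY):
                        p *= b_coeff
                if p > 1.0:
                    p = 1.0
                if p > 0.0 and rand_f64(rng) < p:
                    partner[i] = j
                    partner[j] = i
        elif s == 2:
            j = grid_a[ys[i], xs[i]]
            if j >= 0 and sp[j] == 3 and partner[j] < 0:
                p = min(1.0, p_on_raw[1])
                if p > 0.0 and rand_f64(rng) < p:
                    partner[i] = j
                    partner[j] = i


@njit(cache=True, inline="always")
def _lfa_complex_within(x, y, grid_t, sp, partner, nb_dx, nb_dy, n):
    for k in range(nb_dx.shape[0]):
        qx = x + nb_dx[k]
        qy = y + nb_dy[k]
        if 0 <= qx < n and 0 <= qy < n:
            j = grid_t[qy, qx]
            if j >= 0 and sp[j] == 2 and partner[j] >= 0:
                return True
    return False


@njit(cache=True)
def foci_phase(
    grid_t,
    sp,
    partner,
    active,
    foci_state,
    foci_age,
    snap,
    rng_foci,
    p_nucleate,
    p_nuc_poly,
    p_poly,
    p_decay,
    nb_dx,
    nb_dy,
):
    """One synchronous update of the F-actin foci automaton.

    Transitions read the lattice state at the start of the phase (``snap``):
    TCR–pMHC occupancy nucleates F-actin; colocalized LFA-1–ICAM-1 promotes
    nucleation to nucleation-polymerized; LFA-1–ICAM-1 within the
    neighborhood radius promotes either nucleated state to polymerization;
    every non-empty state self-inhibits with ``p_decay``.
    """
    n = grid_t.shape[0]
    snap[:] = foci_state
    for y in range(n):
        for x in range(n):
            s = snap[y, x]
            i = grid_t[y, x]
            if s == FOCI_EMPTY:
                if i >= 0 and sp[i] == 0 and partner[i] >= 0:
                    if p_nucleate > 0.0 and rand_f64(rng_foci) < p_nucleate:
                        foci_state[y, x] = FOCI_NUCL
                        foci_age[y, x] = 0
                continue
            if active[y, x] == 0:
                continue
            # self-inhibition first; survivors may advance one transition
            if p_decay > 0.0 and rand_f64(rng_foci) < p_decay:
                foci_state[y, x] = FOCI_EMPTY
                foci_age[y, x] = 0
                continue
            ns = s
            if s == FOCI_NUCL:
                colocal = i >= 0 and sp[i] == 2 and partner[i] >= 0
                if colocal:
                    if p_nuc_poly > 0.0 and rand_f64(rng_foci) < p_nuc_poly:
                        ns = FOCI_NUCL_POLY
                elif _lfa_complex_within(x, y, grid_t, sp, partner, nb_dx, nb_dy, n):
                    if p_poly > 0.0 and rand_f64(rng_foci) < p_poly:
                        ns = FOCI_POLY
            elif s == FOCI_NUCL_POLY:
                if _lfa_complex_within(x, y, grid_t, sp, partner, nb_dx, nb_dy, n):
                    if p_poly > 0.0 and rand_f64(rng_foci) < p_poly:
                        ns = FOCI_POLY
            if ns != s:
                foci_state[y, x] = ns
                foci_age[y, x] = 0
            else:
                foci_age[y, x] += 1


@njit(cache=True)
def run_steps(
    n_steps,
    step0,
    grid_t,
    grid_a,
    active,
    sp,
    xs,
    ys,
    partner,
    foci_state,
    foci_age,
    rng,
    rng_foci,
    p_move_sp,
    p_move_pair,
    p_on_raw,
    p_off,
    coupling_enabled,
    sc_short,
    sc_long,
    ss,
    fields,
    kdx,
    kdy,
    kwx,
    kwy,
    sbs_interval,
    cx,
    foci_enabled,
    b_coeff,
    feedback_all,
    p_nucleate,
    p_nuc_poly,
    p_poly,
    p_decay,
    nb_dx,
    nb_dy,
    unit_agents,
    unit_kinds,
    snap,
):
    """Fused multi-step driver: movement → unbinding → binding → foci, per step."""
    for k in range(n_steps):
        step = step0 + k
        if ss > 0.0 and step % sbs_interval == 0:
            compute_sbs_fields(grid_t, sp, xs, ys, partner, fields, kdx, kdy, kwx, kwy)
        move_phase(
            grid_t,
            grid_a,
            active,
            sp,
            xs,
            ys,
            partner,
            rng,
            p_move_sp,
            p_move_pair,
            coupling_enabled,
            sc_short,
            sc_long,
            ss,
            fields,
            cx,
            unit_agents,
            unit_kinds,
        )
        unbind_phase(sp, partner, rng, p_off)
        bind_phase(
            grid_a,
            sp,
            xs,
            ys,
            partner,
            rng,
            p_on_raw,
            foci_enabled,
            foci_state,
            b_coeff,
            feedback_all,
        )
        if foci_enabled:
            foci_phase(
                grid_t,
                sp,
                partner,
                active,
                foci_state,
                foci_age,
                snap,
                rng_foci,
                p_nucleate,
                p_nuc_poly,
                p_poly,
                p_decay,
                nb_dx,
                nb_dy,
            )
    return step0 + n_steps


@njit(cache=True)
def validate_state(grid_t, grid_a, active, sp, xs, ys, partner):
    """Exhaustive state consistency check; returns 0 if sound.

    Codes: 1 grid/table mismatch, 2 agent on blocked node, 3 wrong-side
    agent, 4 occupancy count mismatch, 5 non-mutual partner, 6 bound pair
    not colocalized, 7 invalid species pairing.
    """
    n = grid_t.shape[0]
    n_occupied = 0
    for y in range(n):
        for x in range(n):
            i = grid_t[y, x]
            if i >= 0:
                n_occupied += 1
                if active[y, x] == 0:
                    return 2
                if sp[i] != 0 and sp[i] != 2:
                    return 3
                if xs[i] != x or ys[i] != y:
                    return 1
            j = grid_a[y, x]
            if j >= 0:
                n_occupied += 1
                if active[y, x] == 0:
                    return 2
                if sp[j] != 1 and sp[j] != 3:
                    return 3
                if xs[j] != x or ys[j] != y:
                    return 1
    if n_occupied != sp.shape[0]:
        return 4
    for i in range(sp.shape[0]):
        j = partner[i]
        if j >= 0:
            if partner[j] != i:
                return 5
            if xs[i] != xs[j] or ys[i] != ys[j]:
                return 6
            a, b = sp[i], sp[j]
            lo, hi = (a, b) if a < b else (b, a)
            if not ((lo == 0 and hi == 1) or (lo == 2 and hi == 3)):
                return 7
    return 0
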