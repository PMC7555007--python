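"""Independent oracles used by the test suite.

These deliberately avoid the lattice engine: a well-mixed Gillespie
simulation of reversible A + B ⇌ AB, and a tiny breadth-first cluster
counter.  They provide the reference values the lattice implementation is
checked against.
"""

from __future__ import annotations

import numpy as np


def gillespie_binding(
    n_a: int,
    n_b: int,
    k_bind_per_pair: float,
    k_off: float,
    t_end: float,
    sample_dt: float,
    rng: np.random.Generator,
    t_burn: float = 0.0,
):
    """Exact stochastic simulation of A + B ⇌ AB in a well-mixed volume.

    ``k_bind_per_pair`` is the association propensity of one specific (A, B)
    pair (s⁻¹); total binding propensity is k·nA·nB.  Returns arrays of
    sampled (nA, nB, nAB) at ``sample_dt`` intervals in (t_burn, t_end].
    """
    t = 0.0
    n_ab = 0
    next_sample = max(t_burn, sample_dt)
    samples = []
    while t < t_end:
        a_bind = k_bind_per_pair * (n_a - n_ab) * (n_b - n_ab)
        a_unbind = k_off * n_ab
        a_tot = a_bind + a_unbind
        if a_tot <= 0:
            break
        dt = rng.exponential(1.0 / a_tot)
        t_new = t + dt
        while next_sample <= min(t_new, t_end):
            samples.append((n_a - n_ab, n_b - n_ab, n_ab))
            next_sample += sample_dt
        t = t_new
        if rng.random() < a_bind / a_tot:
            n_ab += 1
        else:
            n_ab -= 1
    while next_sample <= t_end:
        samples.append((n_a - n_ab, n_b - n_ab, n_ab))
        next_sample += sample_dt
    return np.array(samples, dtype=float)


def mean_cellkd_from_samples(samples: np.ndarray, area_um2: float) -> float:
    """Mean of the per-sample [A][B]/[AB] ratio over samples with AB > 0."""
    mask = samples[:, 2] > 0
    ratios = samples[mask, 0] * samples[mask, 1] / samples[mask, 2]
    return float(np.mean(ratios)) / area_um2


def count_clusters_bfs(mask: np.ndarray) -> int:
    """4-connected cluster count by breadth-first search (reference)."""
    seen = np.zeros_like(mask, dtype=bool)
    n_clusters = 0
    ny, nx = mask.shape
    for y0 in range(ny):
        for x0 in range(nx):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            n_clusters += 1
            stack = [(y0, x0)]
            seen[y0, x0] = True
            while stack:
                y, x = stack.pop()
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
    return n_clusters
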