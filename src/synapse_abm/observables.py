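"""Readouts: the in situ dissociation constant cellKD, densities, profiles.

The central observable is the in situ dissociation constant

    cellKD = [TCR_free]·[pMHC_free] / [TCR–pMHC]        (molecules/µm²)

computed from surface densities over the active synapse area.  It is the
inverse of the apparent TCR–pMHC affinity; a decrease with ligand density is
positive cooperativity, an increase negative cooperativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .foci import FociSummary, foci_summary
from .lattice_core import SimulationState

#: fields determined purely by molecular kinetics (used by the B=1 control
#: equivalence check, which excludes foci bookkeeping)
MOLECULAR_FIELDS = (
    "time_s",
    "free_tcr",
    "free_pmhc",
    "bound_tcr_pmhc",
    "free_lfa1",
    "free_icam1",
    "bound_lfa1_icam1",
    "cellkd",
)


def compute_cellkd(free_tcr: float, free_pmhc: float, bound: float) -> float:
    """cellKD = free_TCR·free_pMHC/bound; NaN when no complexes exist.

    All arguments are densities in molecules/µm²; the result is too.  The
    undefined (bound = 0) case is propagated as NaN, i.e. missing data in
    tables, never an exception.
    """
    if free_tcr < 0 or free_pmhc < 0 or bound < 0:
        raise ValueError("densities must be >= 0")
    if bound == 0:
        return math.nan
    return free_tcr * free_pmhc / bound


@dataclass(frozen=True)
class ObservationRecord:
    """Time-stamped densities (molecules/µm² over the active area) and cellKD."""

    time_s: float
    free_tcr: float
    free_pmhc: float
    bound_tcr_pmhc: float
    free_lfa1: float
    free_icam1: float
    bound_lfa1_icam1: float
    cellkd: float
    foci: FociSummary

    def to_row(self) -> dict:
        row = {f: getattr(self, f) for f in MOLECULAR_FIELDS}
        row.update(
            n_nucleation=self.foci.n_nucleation,
            n_nucleation_polymerized=self.foci.n_nucleation_polymerized,
            n_polymerization=self.foci.n_polymerization,
            n_foci=self.foci.n_clusters,
        )
        return row


def record_observation(state: SimulationState) -> ObservationRecord:
    """Count agents by species and bond status and convert to densities."""
    area = state.config.lattice.active_area_um2
    c = state.counts()
    free_tcr = c["TCR"]["free"] / area
    free_pmhc = c["pMHC"]["free"] / area
    bound_tp = c["TCR"]["bound"] / area
    return ObservationRecord(
        time_s=state.clock_s,
        free_tcr=free_tcr,
        free_pmhc=free_pmhc,
        bound_tcr_pmhc=bound_tp,
        free_lfa1=c["LFA1"]["free"] / area,
        free_icam1=c["ICAM1"]["free"] / area,
        bound_lfa1_icam1=c["LFA1"]["bound"] / area,
        cellkd=compute_cellkd(free_tcr, free_pmhc, bound_tp),
        foci=foci_summary(state.foci_state),
    )


def observations_to_frame(records: Iterable[ObservationRecord], **extra) -> pd.DataFrame:
    """Tidy table, one row per record; ``extra`` adds constant columns."""
    df = pd.DataFrame([r.to_row() for r in records])
    for k, v in extra.items():
        df[k] = v
    return df


_PROFILE_COLUMNS = {
    "TCR_free": (0, False),
    "pMHC_free": (1, False),
    "LFA1_free": (2, False),
    "ICAM1_free": (3, False),
    "TCR:pMHC": (0, True),  # counted at the T-side representative
    "LFA1:ICAM1": (2, True),
}


def radial_profile(state: SimulationState, n_bins: int) -> pd.DataFrame:
    """Per-annulus densities from the center to the synapse radius.

    Annuli have equal radial width; densities are counts divided by the
    *actual* node area of the annulus (node count · spacing²), so a uniform
    occupancy yields equal densities in every bin up to sampling noise.
    Counts summed over bins reconstruct whole-domain totals exactly.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lat = state.config.lattice
    c = lat.center
    edges = np.linspace(0.0, lat.synapse_radius_um, n_bins + 1)

    yy, xx = np.nonzero(state.active)
    node_r = np.hypot(xx - c, yy - c) * lat.node_spacing_um
    node_bin = np.clip(np.searchsorted(edges, node_r, side="right") - 1, 0, n_bins - 1)
    node_counts = np.bincount(node_bin, minlength=n_bins)
    bin_area = node_counts * lat.node_spacing_um**2

    out = {"bin": np.arange(n_bins), "r_inner_um": edges[:-1], "r_outer_um": edges[1:],
           "n_nodes": node_counts}
    agent_r = np.hypot(state.xs - c, state.ys - c) * lat.node_spacing_um
    agent_bin = np.clip(np.searchsorted(edges, agent_r, side="right") - 1, 0, n_bins - 1)
    for col, (code, bound) in _PROFILE_COLUMNS.items():
        mask = (state.species == code) & ((state.partner >= 0) == bound)
        counts = np.bincount(agent_bin[mask], minlength=n_bins)
        out[f"{col}_count"] = counts
        with np.errstate(invalid="ignore", divide="ignore"):
            out[col] = np.where(bin_area > 0, counts / np.where(bin_area > 0, bin_area, 1), 0.0)
    return pd.DataFrame(out)


def measure_at_times(
    records: Sequence[ObservationRecord], times: Sequence[float]
) -> list[ObservationRecord]:
    """Observation at each requested time (nearest record at or after it).

    ``records`` must be time-ordered; a requested time past the last record
    raises a range error.
    """
    out = []
    rec_times = [r.time_s for r in records]
    for t in sorted(times):
        idx = None
        for i, rt in enumerate(rec_times):
            if rt >= t - 1e-9:
                idx = i
                break
        if idx is None:
            raise ValueError(f"requested time {t} s beyond recorded trajectory ({rec_times[-1]} s)")
        out.append(records[idx])
    return out
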