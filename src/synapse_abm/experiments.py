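"""In-silico experimental designs: titrations, coupling arrest, B sweeps.

Each experiment is a grid of conditions × replicates.  Replicate seeds are
derived deterministically from ``(base_seed, TCR density, pMHC density,
replicate)`` — deliberately *excluding* the coupling flag and the binding
coefficient B — so arms that differ only in those switches run with paired
seeds and can be compared replicate by replicate.

Replicate aggregation follows the per-simulation convention: cellKD is
computed per replicate and then averaged, with the SD across replicates as
the error estimate.  pMHC densities at or below 1/µm² are auto-flagged as
high-variance (ligand so scarce that receptors fail to find it) and excluded
from minimum-finding.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .config import SimulationConfig, default_config
from .lattice_core import build_initial_state
from .observables import ObservationRecord, observations_to_frame, record_observation

#: pMHC densities at or below this are reported but excluded from minima
LOW_PMHC_FLAG_PER_UM2 = 1.0


def derive_seed(base_seed: int, *key_parts) -> int:
    """Deterministic, platform-independent replicate seed in [0, 2³¹)."""
    key = "|".join(f"{p:.9g}" if isinstance(p, float) else str(p) for p in key_parts)
    return (int(base_seed) + zlib.crc32(key.encode())) % (2**31)


@dataclass(frozen=True)
class ExperimentPlan:
    """A titration design: density grids, replicate count, arms, and timing."""

    pmhc_grid: tuple[float, ...] = tuple(np.geomspace(1.0, 100.0, 8).round(4))
    tcr_grid: tuple[float, ...] = (4.5, 18.0, 55.5)
    tcr_density: float = 18.0  # fixed TCR density for single-curve titrations
    n_replicates: int = 10
    base_seed: int = 0
    duration_s: float = 600.0
    measurement_times_s: tuple[float, ...] = (60.0, 120.0, 300.0, 600.0)
    coupling_enabled: bool = True
    foci_enabled: bool = False
    b: float = 1.0
    b_grid: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 10.0)
    synapse_radius_um: float = 3.5
    config_kwargs: dict = field(default_factory=dict)  # passed to default_config

    def __post_init__(self) -> None:
        if not self.pmhc_grid or not self.tcr_grid:
            raise ValueError("density grids must be non-empty")
        if min(self.pmhc_grid) <= 0 or min(self.tcr_grid) <= 0:
            raise ValueError("densities must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.measurement_times_s and max(self.measurement_times_s) > self.duration_s + 1e-9:
            raise ValueError("measurement times exceed the simulation duration")

    def config_for(
        self,
        pmhc_density: float,
        tcr_density: float | None = None,
        coupling_enabled: bool | None = None,
        b: float | None = None,
        foci_enabled: bool | None = None,
    ) -> SimulationConfig:
        return default_config(
            pmhc_density=pmhc_density,
            tcr_density=self.tcr_density if tcr_density is None else tcr_density,
            synapse_radius_um=self.synapse_radius_um,
            coupling_enabled=self.coupling_enabled if coupling_enabled is None else coupling_enabled,
            foci_enabled=self.foci_enabled if foci_enabled is None else foci_enabled,
            b=self.b if b is None else b,
            **self.config_kwargs,
        )


def run_condition(
    config: SimulationConfig,
    seed: int,
    duration_s: float,
    measurement_times_s: Sequence[float] = (),
    cellkd_window_s: float = 20.0,
    cellkd_sample_s: float = 2.0,
) -> tuple[list[ObservationRecord], list[float]]:
    """One simulation: build, advance, observe.

    Returns ``(records, windowed_cellkd)``: the initial observation plus one
    record per requested measurement time (deduplicated, time-ordered), and
    for each record the per-replicate cellKD estimate — the mean of
    instantaneous cellKD sampled every ``cellkd_sample_s`` over the trailing
    window ``[t − cellkd_window_s, t]``.  The windowed estimate damps the
    shot noise of single-snapshot densities in small contacts; a window of 0
    reduces to the instantaneous value.  Deterministic per seed.
    """
    tau = config.lattice.timestep_s
    n_total = int(round(duration_s / tau))
    target_steps = sorted({int(round(t / tau)) for t in measurement_times_s if t <= duration_s + 1e-9})
    w_steps = max(0, int(round(cellkd_window_s / tau)))
    s_steps = max(1, int(round(cellkd_sample_s / tau)))

    state = build_initial_state(config, seed)
    records = [record_observation(state)]
    windowed = [records[0].cellkd]
    # checkpoints: all sampling instants inside each measurement window
    sample_steps: dict[int, list[int]] = {}
    for tgt in target_steps:
        lo = max(0, tgt - w_steps)
        pts = list(range(tgt, lo - 1, -s_steps))[::-1]
        sample_steps[tgt] = pts
    all_steps = sorted({s for pts in sample_steps.values() for s in pts})

    samples: dict[int, float] = {}
    for step in all_steps:
        if step > n_total:
            break
        if step > state.step_count:
            kinetics.run(state, n_steps=step - state.step_count)
        samples[step] = record_observation(state).cellkd if step != 0 else records[0].cellkd
        if step in target_steps and step > 0:
            records.append(record_observation(state))
    for tgt in target_steps:
        if tgt == 0 or tgt > n_total:
            continue
        vals = np.array([samples[s] for s in sample_steps[tgt] if s in samples])
        vals = vals[np.isfinite(vals)]
        windowed.append(float(np.mean(vals)) if vals.size else float("nan"))
    return records, windowed


@dataclass
class TitrationSummary:
    """Aggregated cellKD over one pMHC-titration curve.

    ``table`` has one row per (pmhc_density, time) with the across-replicate
    mean and SD of cellKD; ``observations`` keeps the per-replicate records.
    """

    table: pd.DataFrame
    observations: pd.DataFrame
    tcr_density: float
    n_replicates: int

    def curve(self, time_s: float) -> pd.DataFrame:
        sub = self.table[np.isclose(self.table["time_s"], time_s)]
        if sub.empty:
            raise ValueError(f"no measurements at t = {time_s} s")
        return sub.sort_values("pmhc_density").reset_index(drop=True)

    def minimum(self, time_s: float) -> "MinimumResult":
        c = self.curve(time_s)
        return detect_interior_minimum(
            c["pmhc_density"].to_numpy(),
            c["mean_cellkd"].to_numpy(),
            c["sd_cellkd"].to_numpy(),
            usable=~c["flagged"].to_numpy(),
        )


@dataclass(frozen=True)
class MinimumResult:
    """Interior-minimum detection outcome for one cellKD-vs-density curve.

    ``present`` is None when fewer than four usable points were available
    (insufficient data).
    """

    present: bool | None
    argmin_density: float
    min_value: float
    pooled_sd: float

    @property
    def insufficient(self) -> bool:
        return self.present is None


def detect_interior_minimum(
    densities: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    usable: np.ndarray | None = None,
) -> MinimumResult:
    """Deterministic interior-minimum test on a mean-cellKD curve.

    The minimum counts as interior when its argmin is not an endpoint of the
    usable grid and both the first and last usable points exceed it by more
    than one pooled SD (root-mean-square of the per-point SDs) — a guard
    against declaring minima inside replicate noise.
    """
    densities = np.asarray(densities, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if usable is None:
        usable = np.ones(densities.shape, dtype=bool)
    usable = np.asarray(usable, dtype=bool) & np.isfinite(means)
    if usable.sum() < 4:
        return MinimumResult(None, float("nan"), float("nan"), float("nan"))
    d = densities[usable]
    m = means[usable]
    s = sds[usable]
    order = np.argsort(d)
    d, m, s = d[order], m[order], s[order]
    k = int(np.argmin(m))
    pooled = float(np.sqrt(np.mean(np.square(np.nan_to_num(s)))))
    interior = 0 < k < len(m) - 1
    deep = (m[0] > m[k] + pooled) and (m[-1] > m[k] + pooled)
    return MinimumResult(bool(interior and deep), float(d[k]), float(m[k]), pooled)


def monotone_nonincreasing_within_sd(curve: pd.DataFrame) -> bool:
    """True if successive usable means never rise by more than one pooled SD."""
    sub = curve[~curve["flagged"]]
    m = sub["mean_cellkd"].to_numpy()
    m = m[np.isfinite(m)]
    if len(m) < 2:
        return True
    pooled = float(np.sqrt(np.nanmean(np.square(sub["sd_cellkd"].to_numpy()))))
    return bool(np.all(np.diff(m) <= pooled))


def curves_within_sd(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    """Pointwise indistinguishability of two titration curves.

    True when, at every usable shared density, the means differ by less than
    the larger of the two replicate SDs (with a small floor for
    zero-variance points).
    """
    merged = a.merge(b, on="pmhc_density", suffixes=("_a", "_b"))
    merged = merged[~(merged["flagged_a"] | merged["flagged_b"])]
    diff = np.abs(merged["mean_cellkd_a"] - merged["mean_cellkd_b"])
    tol = np.maximum(merged["sd_cellkd_a"], merged["sd_cellkd_b"])
    tol = np.maximum(tol, 1e-3 * np.abs(merged["mean_cellkd_a"]))
    ok = diff <= tol
    return bool(ok[np.isfinite(diff)].all())


def _summarize(obs: pd.DataFrame, tcr_density: float, n_replicates: int) -> TitrationSummary:
    value_col = "cellkd_window" if "cellkd_window" in obs.columns else "cellkd"
    rows = []
    for (pmhc, t), grp in obs.groupby(["pmhc_density", "time_s"], sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        all_undefined = finite.size == 0
        rows.append(
            {
                "pmhc_density": pmhc,
                "time_s": t,
                "mean_cellkd": float(np.mean(finite)) if finite.size else np.nan,
                "sd_cellkd": float(np.std(finite, ddof=1)) if finite.size > 1 else np.nan,
                "n_defined": int(finite.size),
                "flagged": bool(all_undefined or pmhc <= LOW_PMHC_FLAG_PER_UM2),
            }
        )
    return TitrationSummary(
        table=pd.DataFrame(rows),
        observations=obs,
        tcr_density=tcr_density,
        n_replicates=n_replicates,
    )


def pmhc_titration(
    plan: ExperimentPlan,
    tcr_density: float | None = None,
    coupling_enabled: bool | None = None,
    b: float | None = None,
    foci_enabled: bool | None = None,
) -> TitrationSummary:
    """Titrate pMHC density at fixed TCR density; mean ± SD cellKD per point."""
    if len(plan.pmhc_grid) < 4:
        raise ValueError("pMHC grid needs at least 4 densities")
    tcr = plan.tcr_density if tcr_density is None else tcr_density
    frames = []
    for pmhc in plan.pmhc_grid:
        cfg = plan.config_for(pmhc, tcr, coupling_enabled, b, foci_enabled)
        for rep in range(plan.n_replicates):
            seed = derive_seed(plan.base_seed, float(tcr), float(pmhc), rep)
            recs, windowed = run_condition(cfg, seed, plan.duration_s, plan.measurement_times_s)
            frame = observations_to_frame(
                recs[1:], pmhc_density=pmhc, tcr_density=tcr, replicate=rep, seed=seed
            )
            frame["cellkd_window"] = windowed[1:]
            frames.append(frame)
    obs = pd.concat(frames, ignore_index=True)
    return _summarize(obs, tcr, plan.n_replicates)


def tcr_titration(
    plan: ExperimentPlan,
    coupling_enabled: bool | None = None,
) -> tuple[dict[float, TitrationSummary], pd.DataFrame]:
    """Repeat the pMHC titration at each TCR density; tabulate the minima.

    Returns per-TCR summaries and a minimum-shift table with one row per TCR
    density: the pMHC density at which the minimum cellKD is reached and the
    minimum value (at the final measurement time).
    """
    if len(plan.tcr_grid) < 1:
        raise ValueError("TCR grid must be non-empty")
    t_final = max(plan.measurement_times_s)
    summaries: dict[float, TitrationSummary] = {}
    rows = []
    for tcr in plan.tcr_grid:
        s = pmhc_titration(plan, tcr_density=tcr, coupling_enabled=coupling_enabled)
        summaries[tcr] = s
        m = s.minimum(t_final)
        rows.append(
            {
                "tcr_density": tcr,
                "argmin_pmhc_density": m.argmin_density,
                "min_cellkd": m.min_value,
                "interior_minimum": m.present,
            }
        )
    return summaries, pd.DataFrame(rows)


def b_sweep(
    plan: ExperimentPlan,
    coupling_enabled: bool | None = None,
) -> dict[float, TitrationSummary]:
    """Titrate pMHC at each binding coefficient B with paired replicate seeds.

    Foci are enabled for every arm (B = 1 is the control: the feedback field
    is identically 1, so its molecular trajectory matches a no-foci run).
    """
    out: dict[float, TitrationSummary] = {}
    for b in plan.b_grid:
        out[b] = pmhc_titration(plan, coupling_enabled=coupling_enabled, b=b, foci_enabled=True)
    return out


def feedback_curves_equivalent(a: TitrationSummary, b: TitrationSummary, time_s: float) -> bool:
    """Indistinguishability of a feedback arm from its control titration.

    True when (i) the minimum cellKD values differ by less than the larger
    replicate SD at their argmin points, and (ii) the mean absolute
    pointwise deviation over usable densities is within the mean per-point
    replicate SD.  This is the curve-level reading of "no change in
    qualitative behavior or in the minimum value": single noisy grid points
    may deviate by about one replicate SD without breaking equivalence, and
    the binary interior-minimum detector — underpowered on the short grids
    used for feedback sweeps — is deliberately not consulted.
    """
    ca, cb = a.curve(time_s), b.curve(time_s)
    ma, mb = a.minimum(time_s), b.minimum(time_s)
    merged = ca.merge(cb, on="pmhc_density", suffixes=("_a", "_b"))
    merged = merged[~(merged["flagged_a"] | merged["flagged_b"])]
    sd_at = lambda c, d: float(c.loc[np.isclose(c["pmhc_density"], d), "sd_cellkd"].iloc[0])
    min_tol = max(sd_at(ca, ma.argmin_density), sd_at(cb, mb.argmin_density))
    if abs(ma.min_value - mb.min_value) > min_tol:
        return False
    diffs = np.abs(merged["mean_cellkd_a"] - merged["mean_cellkd_b"])
    tols = np.maximum(merged["sd_cellkd_a"], merged["sd_cellkd_b"])
    return bool(np.nanmean(diffs) <= np.nanmean(tols))
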