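# synapse-abm

Agent-based lattice simulation of immunological synapse (IS) formation,
built to study **TCR cooperativity**: the density-dependent modulation of
the apparent affinity between T-cell receptors (TCR) and antigenic
peptide–MHC (pMHC) during the first minutes of antigen recognition.

The model represents the T cell–bilayer contact as two paired 2D lattices
(TCR and LFA-1 on the T-cell side; pMHC and ICAM-1 on the bilayer side)
with one molecule per node. Molecules random-walk, bind and unbind with
probabilities derived from kon/koff, and bound complexes feel two empirical
forces: size-based segregation (short TCR–pMHC vs long LFA-1–ICAM-1
complexes repel within a radius R_force) and centripetal transport toward
the synapse center, modeling coupling to contracting F-actin arcs. A third
lattice runs an F-actin foci automaton
(nucleation → nucleation-polymerized → polymerization, with
self-inhibition) whose formed foci feed back on the TCR–pMHC association
probability through a binding coefficient **B** (B > 1 positive, B < 1
negative feedback).

The central readout is the in situ dissociation constant measured from
surface densities over the contact area,

    cellKD = [TCR_free]·[pMHC_free] / [TCR–pMHC]     (molecules/µm²),

the inverse of the apparent affinity. The package reproduces, from the
mechanisms alone (kon and koff never change during a run), the signature
phenotypes of cooperativity: with actin coupling, cellKD falls with pMHC
density to an interior minimum and rises again; arresting the coupling
flattens the curve; the minimum emerges only minutes into contact; its
position shifts to higher pMHC density as TCR density grows; and positive
foci feedback (B > 1) deepens it.

## Worked example

One 2-minute simulation at 20 pMHC/µm² on the default 3.5-µm synapse:

```bash
synapse-abm run --pmhc 20 --seed 3 --duration 120 --times 60,120 --out demo_run
```

prints the observation table it also writes to `demo_run/observations.tsv`:

```
 time_s  free_tcr  free_pmhc  bound_tcr_pmhc  free_lfa1  bound_lfa1_icam1   cellkd  cellkd_window
    0.0 18.007245  20.008050        0.000000  49.994140          0.000000      NaN            NaN
   60.0  7.743375   9.744180       10.263870   6.470136         43.524005 7.351306       8.769384
  120.0  6.781949   8.782754       11.225296   6.106353         43.887788 5.306247       6.526852
```

Reading it: of the 18 TCR/µm² initially present, 10.3/µm² are in TCR–pMHC
complexes after one minute, and cellKD ≈ 7.4 µm⁻² — already below the
intrinsic lattice KD (≈ 15 µm⁻² for the default rates), i.e. the apparent
affinity has been *enhanced* by transport-driven complex accumulation, and
it keeps improving through the second minute (`cellkd_window` is the
shot-noise-damped trailing 20-s average used by the titration driver).
`demo_run/` also contains the resolved config, a plain-text lattice
snapshot, and a synapse image (TCR–pMHC green, LFA-1–ICAM-1 red) showing
the nascent central cluster and adhesion ring.

Titration sweeps (the in-silico experiments) run through the same CLI:

```bash
synapse-abm titrate --mode pmhc --tcr 18 --replicates 10 --seed 42 --out sweep/
synapse-abm titrate --mode b    --no-coupling --out sweep_arrest/
```

or through the library (`ExperimentPlan`, `pmhc_titration`,
`tcr_titration`, `b_sweep`, `detect_interior_minimum`).

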