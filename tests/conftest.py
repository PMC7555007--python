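import dataclasses

import numpy as np
import pytest

from synapse_abm import (
    BindingRule,
    FociParams,
    ForceParams,
    LatticeConfig,
    SimulationConfig,
    SpeciesSpec,
    build_initial_state,
)


def make_config(
    radius_um=1.0,
    spacing_um=0.08,
    tcr=18.0,
    pmhc=20.0,
    lfa1=50.0,
    icam1=50.0,
    tcr_kon=2.4e5,
    tcr_koff=0.4,
    lfa_kon=2e5,
    lfa_koff=0.03,
    d_tcr=0.05,
    d_pmhc=0.1,
    forces=None,
    foci=None,
    binding_scale=1.0,
    complex_diffusion=None,
):
    """Small, fully explicit config for unit tests."""
    return SimulationConfig(
        lattice=LatticeConfig.from_radius(radius_um, node_spacing_um=spacing_um),
        species=(
            SpeciesSpec("TCR", d_tcr, tcr),
            SpeciesSpec("pMHC", d_pmhc, pmhc),
            SpeciesSpec("LFA1", 0.05, lfa1),
            SpeciesSpec("ICAM1", 0.1, icam1),
        ),
        rules=(
            BindingRule("TCR:pMHC", tcr_kon, tcr_koff),
            BindingRule("LFA1:ICAM1", lfa_kon, lfa_koff),
        ),
        forces=forces or ForceParams(sbs_strength=0.0, coupling_enabled=False),
        foci=foci or FociParams(),
        binding_scale=binding_scale,
        complex_diffusion_um2_s=complex_diffusion,
    )


@pytest.fixture
def small_state():
    """~350-agent disk of radius 1 µm, forces off, deterministic seed."""
    return build_initial_state(make_config(), seed=123)


@pytest.fixture
def empty_config():
    return make_config(tcr=0.0, pmhc=0.0, lfa1=0.0, icam1=0.0)


def with_forces(cfg, **kwargs):
    return dataclasses.replace(cfg, forces=ForceParams(**kwargs))


def place_bound_pairs(state, n_pairs, pair=("TCR", "pMHC"), rng_seed=0):
    """Scatter n_pairs pre-bound complexes on free colocalized nodes."""
    from synapse_abm import add_agent, bind_pair

    rng = np.random.default_rng(rng_seed)
    free = np.argwhere((state.grid_t == -1) & (state.grid_a == -1) & (state.active == 1))
    idx = rng.choice(len(free), size=n_pairs, replace=False)
    for y, x in free[idx]:
        add_agent(state, pair[0], (int(x), int(y)))
        add_agent(state, pair[1], (int(x), int(y)))
        bind_pair(state, (int(x), int(y)))
    return state
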