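"""Configuration objects: lattice geometry, species, binding rules, forces, foci.

Units follow membrane-biophysics convention throughout: lengths in µm,
densities in molecules/µm², diffusion coefficients in µm²/s, on-rates in
M⁻¹s⁻¹, off-rates in s⁻¹, time in seconds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
import yaml

AVOGADRO = 6.02214076e23  # mol⁻¹

#: canonical species order; also the integer codes used on the lattices
SPECIES_NAMES = ("TCR", "pMHC", "LFA1", "ICAM1")
T_CELL_SIDE = "T"  # TCR, LFA1 live on the T-cell membrane lattice
APC_SIDE = "APC"  # pMHC, ICAM1 live on the bilayer/APC lattice
_SIDE_OF = {"TCR": T_CELL_SIDE, "pMHC": APC_SIDE, "LFA1": T_CELL_SIDE, "ICAM1": APC_SIDE}
_SIZE_OF = {"TCR": "short", "pMHC": "short", "LFA1": "long", "ICAM1": "long"}

#: complex classes (pair index used throughout the kernels)
PAIR_NAMES = ("TCR:pMHC", "LFA1:ICAM1")
PAIR_TCR_PMHC = 0
PAIR_LFA_ICAM = 1


class ConfigError(ValueError):
    """Raised for inconsistent or unknown configuration values."""


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and clock of the paired membrane lattices.

    The simulated contact is a circular domain (the nascent synapse) of
    radius ``synapse_radius_um`` inscribed in a square lattice of
    ``nodes_per_side`` nodes with spacing ``node_spacing_um``.  Nodes outside
    the disk are permanently blocked.  ``membrane_gap_um`` is the height of
    the inter-membrane reaction volume used to convert a molar on-rate into
    a per-step binding probability.
    """

    nodes_per_side: int
    node_spacing_um: float = 0.07
    synapse_radius_um: float = 3.5
    timestep_s: float = 0.01
    membrane_gap_um: float = 0.015

    def __post_init__(self) -> None:
        if self.nodes_per_side < 8:
            raise ConfigError("nodes_per_side must be >= 8")
        if self.node_spacing_um <= 0 or self.timestep_s <= 0:
            raise ConfigError("node_spacing_um and timestep_s must be positive")
        if self.membrane_gap_um <= 0:
            raise ConfigError("membrane_gap_um must be positive")
        if self.synapse_radius_um > self.nodes_per_side * self.node_spacing_um / 2:
            raise ConfigError(
                "synapse_radius_um exceeds half the lattice side "
                f"({self.synapse_radius_um} > {self.nodes_per_side * self.node_spacing_um / 2})"
            )

    @classmethod
    def from_radius(
        cls,
        synapse_radius_um: float,
        node_spacing_um: float = 0.07,
        timestep_s: float = 0.01,
        membrane_gap_um: float = 0.015,
    ) -> "LatticeConfig":
        """Smallest square lattice holding the disk plus a blocked border ring."""
        n = 2 * math.ceil(synapse_radius_um / node_spacing_um) + 3
        return cls(
            nodes_per_side=max(n, 8),
            node_spacing_um=node_spacing_um,
            synapse_radius_um=synapse_radius_um,
            timestep_s=timestep_s,
            membrane_gap_um=membrane_gap_um,
        )

    @property
    def interaction_volume_um3(self) -> float:
        """Per-node reaction volume V = spacing² · gap, in µm³."""
        return self.node_spacing_um**2 * self.membrane_gap_um

    @property
    def interaction_volume_l(self) -> float:
        return self.interaction_volume_um3 * 1e-15  # 1 µm³ = 1e-15 L

    @property
    def active_area_um2(self) -> float:
        return math.pi * self.synapse_radius_um**2

    @property
    def center(self) -> float:
        """Center coordinate (same for x and y), in node units."""
        return (self.nodes_per_side - 1) / 2.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One membrane molecule species.

    ``side`` and ``size_class`` are fixed by the biology (TCR/pMHC are the
    short pair, LFA-1/ICAM-1 the long adhesion pair) and are derived from the
    name; passing them explicitly is allowed but must agree.
    """

    name: str
    diffusion_um2_s: float
    density_per_um2: float
    side: str = ""
    size_class: str = ""

    def __post_init__(self) -> None:
        if self.name not in SPECIES_NAMES:
            raise ConfigError(f"unknown species name {self.name!r}; expected one of {SPECIES_NAMES}")
        if self.density_per_um2 < 0 or self.diffusion_um2_s < 0:
            raise ConfigError(f"{self.name}: density and diffusion coefficient must be >= 0")
        expected_side = _SIDE_OF[self.name]
        expected_size = _SIZE_OF[self.name]
        if self.side and self.side != expected_side:
            raise ConfigError(f"{self.name} lives on side {expected_side!r}, got {self.side!r}")
        if self.size_class and self.size_class != expected_size:
            raise ConfigError(f"{self.name} is size class {expected_size!r}, got {self.size_class!r}")
        object.__setattr__(self, "side", expected_side)
        object.__setattr__(self, "size_class", expected_size)

    def move_probability(self, lattice: LatticeConfig) -> float:
        """Per-step random-walk move probability 4·D·τ/a²."""
        return 4.0 * self.diffusion_um2_s * lattice.timestep_s / lattice.node_spacing_um**2

    def validate_stability(self, lattice: LatticeConfig) -> None:
        p = self.move_probability(lattice)
        if p > 1.0:
            raise ConfigError(
                f"{self.name}: move probability 4·D·τ/a² = {p:.3f} exceeds 1; "
                "reduce the timestep or the diffusion coefficient"
            )

    @property
    def code(self) -> int:
        return SPECIES_NAMES.index(self.name)


@dataclass(frozen=True)
class BindingRule:
    """Reversible binding between a colocalized receptor–ligand pair.

    The molar on-rate is converted to a characteristic association time
    τ_on = V·N_A/kon for the per-node interaction volume V; a colocalized
    free pair then binds with per-step probability p_on = B·τ/τ_on (clamped
    to 1), and a complex dissociates with p_off = 1 − exp(−koff·τ).
    """

    pair: str  # "TCR:pMHC" or "LFA1:ICAM1"
    kon_per_m_s: float
    koff_per_s: float

    def __post_init__(self) -> None:
        if self.pair not in PAIR_NAMES:
            raise ConfigError(f"unknown binding pair {self.pair!r}; expected one of {PAIR_NAMES}")
        if self.kon_per_m_s < 0 or self.koff_per_s < 0:
            raise ConfigError(f"{self.pair}: rates must be >= 0")

    @property
    def pair_index(self) -> int:
        return PAIR_NAMES.index(self.pair)

    @property
    def species(self) -> tuple[str, str]:
        a, b = self.pair.split(":")
        return a, b

    def tau_on_s(self, lattice: LatticeConfig) -> float:
        """τ_on = V·N_A/kon in seconds (inf when kon = 0)."""
        if self.kon_per_m_s == 0:
            return math.inf
        return lattice.interaction_volume_l * AVOGADRO / self.kon_per_m_s

    def p_on(self, lattice: LatticeConfig, b_effective: float = 1.0) -> float:
        """Per-step association probability, clamped to [0, 1]."""
        tau_on = self.tau_on_s(lattice)
        if math.isinf(tau_on):
            return 0.0
        return min(1.0, max(0.0, b_effective * lattice.timestep_s / tau_on))

    def p_off(self, lattice: LatticeConfig) -> float:
        """Per-step dissociation probability 1 − exp(−koff·τ)."""
        return -math.expm1(-self.koff_per_s * lattice.timestep_s)


@dataclass(frozen=True)
class ForceParams:
    """Deterministic movement biases acting on bound complexes.

    Size-based segregation (SBS) repels complexes of different size classes
    within ``r_force_um``.  Centripetal transport models coupling of
    complexes to contracting F-actin arcs; its strength is the default drift
    bias for the short TCR–pMHC class, with the long adhesion class coupled
    more weakly (``centripetal_strength_long``).  ``coupling_enabled=False``
    switches centripetal transport off entirely (the in-silico actin-arrest
    experiment); SBS is controlled by its strength alone.
    """

    r_force_um: float = 0.5
    sbs_strength: float = 0.15
    centripetal_strength: float = 0.5
    centripetal_strength_long: float = 0.1
    coupling_enabled: bool = True
    sbs_kernel: str = "uniform"  # or "inverse_r"
    sbs_update_interval: int = 10  # steps between SBS field refreshes

    def __post_init__(self) -> None:
        if self.r_force_um < 0:
            raise ConfigError("r_force_um must be >= 0")
        for s in (self.sbs_strength, self.centripetal_strength, self.centripetal_strength_long):
            if not 0.0 <= s <= 1.0:
                raise ConfigError("force strengths must lie in [0, 1]")
        if self.sbs_kernel not in ("uniform", "inverse_r"):
            raise ConfigError("sbs_kernel must be 'uniform' or 'inverse_r'")
        if self.sbs_update_interval < 1:
            raise ConfigError("sbs_update_interval must be >= 1")


@dataclass(frozen=True)
class FociParams:
    """F-actin foci automaton parameters and the binding-feedback coefficient.

    Per node the automaton has states empty → nucleation →
    nucleation-polymerized → polymerization; formed polymerization nodes are
    the foci and multiply the TCR–pMHC association probability by ``b``
    (B > 1 positive, B < 1 negative feedback).  All non-empty states
    self-inhibit (revert to empty) with ``p_decay`` per step.
    """

    enabled: bool = False
    r_neighborhood_um: float = 0.24
    p_nucleate: float = 0.02
    p_nuc_polymerize: float = 0.1
    p_polymerize: float = 0.2
    p_decay: float = 0.05
    b: float = 1.0
    feedback_states: str = "polymerization"  # or "all"

    def __post_init__(self) -> None:
        for p in (self.p_nucleate, self.p_nuc_polymerize, self.p_polymerize, self.p_decay):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("foci transition probabilities must lie in [0, 1]")
        if self.r_neighborhood_um < 0:
            raise ConfigError("r_neighborhood_um must be >= 0")
        if self.b < 0:
            raise ConfigError("binding coefficient b must be >= 0")
        if self.feedback_states not in ("polymerization", "all"):
            raise ConfigError("feedback_states must be 'polymerization' or 'all'")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, self-contained description of one simulation run."""

    lattice: LatticeConfig
    species: tuple[SpeciesSpec, ...]
    rules: tuple[BindingRule, ...]
    forces: ForceParams = field(default_factory=ForceParams)
    foci: FociParams = field(default_factory=FociParams)
    binding_scale: float = 1.0  # global multiplier on every p_on (0 disables binding)
    complex_diffusion_um2_s: dict | None = None  # per pair name; default: slower partner

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate species in config")
        for s in self.species:
            s.validate_stability(self.lattice)
        for r in self.rules:
            for sp in r.species:
                if sp not in names:
                    raise ConfigError(f"binding rule {r.pair} references missing species {sp}")
        if self.binding_scale < 0:
            raise ConfigError("binding_scale must be >= 0")

    def species_by_name(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise ConfigError(f"species {name!r} not in config")

    def rule_for(self, pair: str) -> BindingRule | None:
        for r in self.rules:
            if r.pair == pair:
                return r
        return None

    def complex_diffusion(self, pair: str) -> float:
        """Diffusion coefficient of a bound pair (default: the slower partner)."""
        if self.complex_diffusion_um2_s and pair in self.complex_diffusion_um2_s:
            return float(self.complex_diffusion_um2_s[pair])
        a, b = pair.split(":")
        try:
            da = self.species_by_name(a).diffusion_um2_s
            db = self.species_by_name(b).diffusion_um2_s
        except ConfigError:
            return 0.0
        return min(da, db)

    # -- plain-text round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = [dataclasses.asdict(s) for s in self.species]
        d["rules"] = [dataclasses.asdict(r) for r in self.rules]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            lattice=LatticeConfig(**d["lattice"]),
            species=tuple(SpeciesSpec(**s) for s in d["species"]),
            rules=tuple(BindingRule(**r) for r in d["rules"]),
            forces=ForceParams(**d.get("forces", {})),
            foci=FociParams(**d.get("foci", {})),
            binding_scale=d.get("binding_scale", 1.0),
            complex_diffusion_um2_s=d.get("complex_diffusion_um2_s"),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(
    pmhc_density: float = 13.9,
    tcr_density: float = 18.0,
    lfa1_density: float = 50.0,
    icam1_density: float = 50.0,
    synapse_radius_um: float = 3.5,
    timestep_s: float = 0.01,
    node_spacing_um: float = 0.08,
    coupling_enabled: bool = True,
    foci_enabled: bool = False,
    b: float = 1.0,
    tcr_kon: float = 2.4e5,
    tcr_koff: float = 0.4,
    complex_diffusion: float = 0.005,
) -> SimulationConfig:
    """Reference study conditions.

    TCR at 18/µm² (the reference density of the titration experiments), the
    adhesion pair at 50/µm² each, diffusion coefficients and rate constants
    at literature-typical membrane-protein values, and bound complexes
    slowed by their size and cytoskeletal drag (see the methods note for the
    rationale behind every default).
    """
    lattice = LatticeConfig.from_radius(
        synapse_radius_um, node_spacing_um=node_spacing_um, timestep_s=timestep_s
    )
    species = (
        SpeciesSpec("TCR", diffusion_um2_s=0.05, density_per_um2=tcr_density),
        SpeciesSpec("pMHC", diffusion_um2_s=0.1, density_per_um2=pmhc_density),
        SpeciesSpec("LFA1", diffusion_um2_s=0.05, density_per_um2=lfa1_density),
        SpeciesSpec("ICAM1", diffusion_um2_s=0.1, density_per_um2=icam1_density),
    )
    rules = (
        BindingRule("TCR:pMHC", kon_per_m_s=tcr_kon, koff_per_s=tcr_koff),
        BindingRule("LFA1:ICAM1", kon_per_m_s=2e5, koff_per_s=0.03),
    )
    return SimulationConfig(
        lattice=lattice,
        species=species,
        rules=rules,
        forces=ForceParams(coupling_enabled=coupling_enabled),
        foci=FociParams(enabled=foci_enabled, b=b),
        complex_diffusion_um2_s={
            "TCR:pMHC": complex_diffusion,
            "LFA1:ICAM1": complex_diffusion,
        },
    )
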