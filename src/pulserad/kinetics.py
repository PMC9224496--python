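"""Mass-action kinetics of the HO•-induced oxidation schemes.

The reaction networks encode the accepted mechanism of thioether
one-electron oxidation in N₂O-saturated water:

* HO• partitions between addition at sulfur (the hydroxysulfuranyl
  adduct, HOS) and direct H-abstraction channels (aC1, aC2, aS).
* HOS eliminates HO⁻ in a first-order step (k_d = 5.6×10⁵ s⁻¹) to give
  the monomeric sulfur radical cation (Scat ≡ S•⁺).
* S•⁺ is at a crossroad: association with a second substrate molecule
  gives the S∴S dimer cation (SS, reversible), α-deprotonation gives
  aS, and intramolecular cyclisation gives S∴N (SN, methionine-type
  backbone spacing) or S∴O (SO, cysteine-type spacing, fast:
  ≥ 6×10⁷ s⁻¹) species, which in turn release carbon radicals.
* For the shorter side chain an additional carbonyl-assisted decay of
  HOS leads directly to SO, bypassing S•⁺.
* H• adds to sulfur (1.7×10⁹ M⁻¹ s⁻¹); the sulfuranyl radical
  fragments to the desulfurised product and CH₃S•, which couples with
  the carbon radicals (the adduct "footprint" chemistry).

Rate constants that are not fixed by the literature (partition
fractions, deprotonation, cyclisation/reverse steps, the generic
radical–radical sink) are explicit defaults in ``DEFAULT_RATES_C1`` /
``DEFAULT_RATES_C2`` and can be overridden; see docs/methods.md for the
rationale of each value.  Equilibria are realised as explicit
forward/reverse elementary pairs, never as equilibrium-constant
shortcuts.  Integration is deterministic stiff ODE (rates span
10⁵–10¹⁰); no stochastic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .profiles import YieldProfile
from .yields import PrimaryYields, n2o_ho_yield

__all__ = [
    "Reaction",
    "ReactionScheme",
    "SimTrace",
    "SimulationError",
    "DEFAULT_RATES_C1",
    "DEFAULT_RATES_C2",
    "DEFAULT_RATES_H",
    "RADICAL_SPECIES",
    "scheme_compound1",
    "scheme_compound2",
    "scheme_h_atom",
    "simulate",
    "trace_to_yields",
]

#: Transient radical species tracked by the optical experiment.
RADICAL_SPECIES = ("HOS", "Scat", "SS", "SN", "SO", "aS", "aC1", "aC2")


class SimulationError(RuntimeError):
    """The stiff integrator failed to converge."""


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action step (first or second order).

    ``k`` is in s⁻¹ for one reactant and M⁻¹ s⁻¹ for two.  Bimolecular
    steps with a partner held at fixed concentration (substrate at
    0.2 mM) behave as pseudo-first-order; the partner is flagged through
    the scheme's ``fixed`` set.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("a reaction has 1 or 2 reactants")
        if self.k < 0:
            raise ValueError("rate constant must be >= 0")

    @property
    def order(self) -> int:
        return len(self.reactants)


@dataclass
class ReactionScheme:
    """Species, elementary reactions, and initial/fixed concentrations."""

    species: tuple[str, ...]
    reactions: list[Reaction]
    initial: dict[str, float] = field(default_factory=dict)
    fixed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.fixed = frozenset(self.fixed)
        declared = set(self.species)
        for rxn in self.reactions:
            undeclared = (set(rxn.reactants) | set(rxn.products)) - declared
            if undeclared:
                raise ValueError(f"reaction {rxn.label!r} references undeclared {undeclared}")
        for sp, c0 in self.initial.items():
            if sp not in declared:
                raise ValueError(f"initial concentration for undeclared species {sp!r}")
            if c0 < 0:
                raise ValueError(f"negative initial concentration for {sp!r}")
        if not self.fixed <= declared:
            raise ValueError(f"fixed species {self.fixed - declared} undeclared")

    def rate_of(self, label: str) -> float:
        for rxn in self.reactions:
            if rxn.label == label:
                return rxn.k
        raise KeyError(f"no reaction labelled {label!r}")

    # -- persistence (YAML/JSON-compatible mapping) --

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "species": list(self.species),
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "k": r.k,
                    "label": r.label,
                }
                for r in self.reactions
            ],
            "initial": dict(self.initial),
            "fixed": sorted(self.fixed),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReactionScheme":
        return cls(
            species=tuple(payload["species"]),
            reactions=[
                Reaction(
                    tuple(r["reactants"]), tuple(r["products"]),
                    float(r["k"]), str(r.get("label", "")),
                )
                for r in payload["reactions"]
            ],
            initial={k: float(v) for k, v in payload.get("initial", {}).items()},
            fixed=frozenset(payload.get("fixed", ())),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ReactionScheme":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimTrace:
    """Integrated concentration trajectories, M, on an ascending time grid."""

    times: np.ndarray
    species: tuple[str, ...]
    conc: np.ndarray

    def conc_of(self, species: str) -> np.ndarray:
        try:
            j = self.species.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in trace") from None
        return self.conc[:, j]


# ---------------------------------------------------------------------------
# Default rate tables.  Printed literature constants are marked; the rest
# are package defaults within the accepted "typical value" ranges for
# these steps (see docs/methods.md, table of kinetic defaults).

DEFAULT_RATES_C1: dict[str, float] = {
    "k_add": 1.0e10,     # HO + substrate, total (typical diffusion-limited)
    "f_adduct": 0.75,    # fraction of HO flux through the HOS adduct
    "f_ac1": 0.15,       # direct abstraction at backbone C-alpha
    "f_as": 0.05,        # direct abstraction alpha to sulfur
    "f_ac2": 0.05,       # direct abstraction at the N-methyl amide
    "k_d": 5.6e5,        # HOS -> Scat + HO- (printed, s^-1)
    "k_ss_f": 1.0e8,     # Scat + substrate -> SS (typical, M^-1 s^-1)
    "k_ss_r": 1.0e4,     # SS -> Scat + substrate
    "k_dep": 2.0e5,      # Scat -> aS (alpha-deprotonation)
    "k_sn_f": 8.0e4,     # Scat -> SN (cyclisation)
    "k_sn_r": 1.0e4,     # SN -> Scat
    "k_sn_ac2": 2.0e4,   # SN -> aC2
    "k_sn_ac1": 1.0e4,   # SN -> aC1
    "k_rr": 1.0e9,       # generic radical-radical sink (M^-1 s^-1)
}

DEFAULT_RATES_C2: dict[str, float] = {
    "k_add": 1.0e10,
    "f_adduct": 0.70,
    "f_as": 0.20,
    "f_ac2": 0.10,
    "k_d": 5.6e5,        # printed, same spontaneous HO- elimination
    "k_hos_so": 1.0e6,   # HOS -> SO, carbonyl-assisted direct channel
    "k_so_f": 6.0e7,     # Scat -> SO (printed lower limit >6e7 s^-1)
    "k_dep": 5.0e7,      # Scat -> aS (fast deprotonation, shorter chain)
    "k_ss_f": 1.0e8,
    "k_ss_r": 1.0e4,
    "k_so_ac2": 3.0e4,   # SO -> aC2
    "k_rr": 1.0e9,
}

DEFAULT_RATES_H: dict[str, float] = {
    "k_h_add": 1.7e9,    # H + substrate -> sulfuranyl (printed, M^-1 s^-1)
    "k_frag": 1.0e6,     # sulfuranyl -> desulfurised product + CH3S
    "k_ch3s": 1.0e9,     # CH3S + C-radical -> adduct
}


def _merged(defaults: Mapping[str, float], overrides: Mapping[str, float] | None) -> dict:
    rates = dict(defaults)
    if overrides:
        unknown = set(overrides) - set(rates)
        if unknown:
            raise KeyError(f"unknown rate parameters: {sorted(unknown)}")
        rates.update(overrides)
    return rates


def _radical_sinks(radicals: Sequence[str], k_rr: float) -> list[Reaction]:
    """All unordered radical-radical terminations funnelled into one sink."""
    out = []
    for i, a in enumerate(radicals):
        for b in radicals[i:]:
            out.append(Reaction((a, b), ("Prod",), k_rr, f"sink {a}+{b}"))
    return out


def _initial_radicals(dose: float, primary: PrimaryYields, with_h: bool) -> dict[str, float]:
    init = {"HO": n2o_ho_yield(primary) * 1e-6 * dose}
    if with_h:
        init["H"] = primary.g_h * 1e-6 * dose
    return init


def scheme_compound1(overrides: Mapping[str, float] | None = None, *,
                     dose: float = 11.0, substrate_conc: float = 2e-4,
                     primary: PrimaryYields = PrimaryYields(),
                     include_sinks: bool = True) -> ReactionScheme:
    """Oxidation network for the methionine-type derivative (S∴N channel).

    HO• either adds at sulfur or abstracts H directly; HOS decays to S•⁺
    (k_d printed); S•⁺ partitions between reversible SS association,
    deprotonation to aS, and reversible SN cyclisation which releases
    aC1/aC2.  The substrate is held fixed at ``substrate_conc``.
    """
    r = _merged(DEFAULT_RATES_C1, overrides)
    species = ("HO", "M", "HOS", "Scat", "SS", "SN", "aS", "aC1", "aC2", "Prod")
    rxns = [
        Reaction(("HO", "M"), ("HOS",), r["f_adduct"] * r["k_add"], "HO addition"),
        Reaction(("HO", "M"), ("aC1",), r["f_ac1"] * r["k_add"], "direct abstraction aC1"),
        Reaction(("HO", "M"), ("aS",), r["f_as"] * r["k_add"], "direct abstraction aS"),
        Reaction(("HO", "M"), ("aC2",), r["f_ac2"] * r["k_add"], "direct abstraction aC2"),
        Reaction(("HOS",), ("Scat",), r["k_d"], "HOS decay"),
        Reaction(("Scat", "M"), ("SS",), r["k_ss_f"], "SS formation"),
        Reaction(("SS",), ("Scat", "M"), r["k_ss_r"], "SS dissociation"),
        Reaction(("Scat",), ("aS",), r["k_dep"], "deprotonation"),
        Reaction(("Scat",), ("SN",), r["k_sn_f"], "SN formation"),
        Reaction(("SN",), ("Scat",), r["k_sn_r"], "SN ring opening"),
        Reaction(("SN",), ("aC2",), r["k_sn_ac2"], "SN to aC2"),
        Reaction(("SN",), ("aC1",), r["k_sn_ac1"], "SN to aC1"),
    ]
    if include_sinks and r["k_rr"] > 0:
        rxns += _radical_sinks(("HOS", "Scat", "SS", "SN", "aS", "aC1", "aC2"), r["k_rr"])
    initial = _initial_radicals(dose, primary, with_h=False)
    initial["M"] = substrate_conc
    return ReactionScheme(species, rxns, initial, frozenset({"M"}))


def scheme_compound2(overrides: Mapping[str, float] | None = None, *,
                     dose: float = 11.0, substrate_conc: float = 2e-4,
                     primary: PrimaryYields = PrimaryYields(),
                     include_sinks: bool = True) -> ReactionScheme:
    """Oxidation network for the S-methyl-cysteine-type derivative (S∴O channel).

    Differs from the methionine-type network by a carbonyl-assisted
    direct HOS → SO decay, a fast S•⁺ → SO cyclisation (≥6×10⁷ s⁻¹),
    fast deprotonation, no SN channel and no aC1 formation.  SS
    association is retained but is negligible at these rates.
    """
    r = _merged(DEFAULT_RATES_C2, overrides)
    species = ("HO", "M", "HOS", "Scat", "SS", "SO", "aS", "aC2", "Prod")
    rxns = [
        Reaction(("HO", "M"), ("HOS",), r["f_adduct"] * r["k_add"], "HO addition"),
        Reaction(("HO", "M"), ("aS",), r["f_as"] * r["k_add"], "direct abstraction aS"),
        Reaction(("HO", "M"), ("aC2",), r["f_ac2"] * r["k_add"], "direct abstraction aC2"),
        Reaction(("HOS",), ("Scat",), r["k_d"], "HOS decay"),
        Reaction(("HOS",), ("SO",), r["k_hos_so"], "HOS to SO (carbonyl-assisted)"),
        Reaction(("Scat",), ("SO",), r["k_so_f"], "SO formation"),
        Reaction(("Scat",), ("aS",), r["k_dep"], "deprotonation"),
        Reaction(("Scat", "M"), ("SS",), r["k_ss_f"], "SS formation"),
        Reaction(("SS",), ("Scat", "M"), r["k_ss_r"], "SS dissociation"),
        Reaction(("SO",), ("aC2",), r["k_so_ac2"], "SO to aC2"),
    ]
    if include_sinks and r["k_rr"] > 0:
        rxns += _radical_sinks(("HOS", "Scat", "SS", "SO", "aS", "aC2"), r["k_rr"])
    initial = _initial_radicals(dose, primary, with_h=False)
    initial["M"] = substrate_conc
    return ReactionScheme(species, rxns, initial, frozenset({"M"}))


def scheme_h_atom(compound: int, overrides: Mapping[str, float] | None = None, *,
                  dose: float = 11.0, substrate_conc: float = 2e-4,
                  primary: PrimaryYields = PrimaryYields()) -> ReactionScheme:
    """H-atom side chemistry: sulfuranyl formation, desulfurisation, CH₃S• coupling.

    A standalone fragment: H• adds at sulfur (1.7×10⁹ M⁻¹ s⁻¹), the
    sulfuranyl radical fragments into the desulfurised product and
    CH₃S•, and CH₃S• couples with each carbon radical of the compound.
    """
    if compound not in (1, 2):
        raise ValueError("compound must be 1 or 2")
    r = _merged(DEFAULT_RATES_H, overrides)
    c_radicals = ("aS", "aC1", "aC2") if compound == 1 else ("aS", "aC2")
    species = ("H", "M", "SulfH", "CH3S", "Desulf") + c_radicals + tuple(
        f"Adduct_{c}" for c in c_radicals
    )
    rxns = [
        Reaction(("H", "M"), ("SulfH",), r["k_h_add"], "H addition at S"),
        Reaction(("SulfH",), ("Desulf", "CH3S"), r["k_frag"], "desulfurisation"),
    ]
    for c in c_radicals:
        rxns.append(Reaction(("CH3S", c), (f"Adduct_{c}",), r["k_ch3s"], f"CH3S adduct {c}"))
    initial = {"H": primary.g_h * 1e-6 * dose, "M": substrate_conc}
    return ReactionScheme(species, rxns, initial, frozenset({"M"}))


def simulate(scheme: ReactionScheme, t_grid, *, method: str = "LSODA",
             rtol: float = 1e-8, atol: float = 1e-14) -> SimTrace:
    """Integrate a scheme on an ascending time grid (s).

    Deterministic mass-action ODE with an analytic Jacobian; fixed
    species are clamped by zeroing their net rate.  A stiff-capable
    method is required (default LSODA) because the rate constants span
    five orders of magnitude.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D and strictly ascending")
    if t[0] < 0:
        raise ValueError("t_grid must start at >= 0")
    species = list(scheme.species)
    index = {s: i for i, s in enumerate(species)}
    n_sp, n_rx = len(species), len(scheme.reactions)
    y0 = np.array([scheme.initial.get(s, 0.0) for s in species])

    ks = np.array([rx.k for rx in scheme.reactions])
    r_idx = [tuple(index[s] for s in rx.reactants) for rx in scheme.reactions]
    stoich = np.zeros((n_sp, n_rx))
    for j, rx in enumerate(scheme.reactions):
        for s in rx.reactants:
            stoich[index[s], j] -= 1.0
        for s in rx.products:
            stoich[index[s], j] += 1.0
    for s in scheme.fixed:
        stoich[index[s], :] = 0.0

    def rates(y: np.ndarray) -> np.ndarray:
        v = ks.copy()
        for j, idx in enumerate(r_idx):
            for i in idx:
                v[j] *= y[i]
        return v

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return stoich @ rates(y)

    def jac(_t: float, y: np.ndarray) -> np.ndarray:
        dv = np.zeros((n_rx, n_sp))
        for j, idx in enumerate(r_idx):
            if len(idx) == 1:
                dv[j, idx[0]] += ks[j]
            else:
                i0, i1 = idx
                dv[j, i0] += ks[j] * y[i1]
                dv[j, i1] += ks[j] * y[i0]
        return stoich @ dv

    if t[-1] == 0.0:
        return SimTrace(t, tuple(species), y0[None, :].copy())
    sol = solve_ivp(rhs, (0.0, t[-1]), y0, t_eval=t, method=method,
                    rtol=rtol, atol=atol, jac=jac)
    if not sol.success:
        raise SimulationError(
            f"integrator {method} failed: {sol.message}; try method='BDF' "
            f"or relax rtol (currently {rtol:g})"
        )
    return SimTrace(t, tuple(species), sol.y.T)


def trace_to_yields(trace: SimTrace, dose: float, *, density: float = 1.0,
                    species: Sequence[str] | None = None) -> YieldProfile:
    """Convert a concentration trace to G-values: G_j(t) = c_j(t)/(dose·10⁻⁶·ρ)."""
    if dose <= 0:
        raise ValueError("dose must be > 0")
    names = tuple(species) if species is not None else trace.species
    g = np.column_stack([trace.conc_of(s) for s in names]) / (1e-6 * dose * density)
    return YieldProfile(trace.times, names, g)
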