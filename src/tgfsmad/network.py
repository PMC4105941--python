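"""Compartmental mass-action reaction networks.

A :class:`ReactionNetwork` is the executable core of every pathway variant:
a list of species with compartment labels and initial concentrations, a list
of strictly mass-action reactions, and a named parameter set.  Nuclear
species are stored as cytoplasm-volume-relative concentrations (absolute
nuclear concentration times V_nuc/V_cyt), which makes conservation sums
directly additive across compartments; the volume ratio therefore enters
only when rate constants are derived from per-volume literature rates,
never inside the right-hand side.  The extracellular medium is handled the
same way (ligand stored as amount per cytoplasmic volume), so ligand
depletion by receptor binding is ordinary mass action.

Rate laws are strictly mass action: rate = k * prod(reactant and modifier
concentrations), with zeroth-order (empty reactant set) allowed only for
synthesis reactions.  Reversible reactions are always represented as two
irreversible reactions with separately named rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

COMPARTMENTS = ("extracellular", "cytoplasm", "early_endosome", "caveolae", "nucleus")


class NetworkConfigError(ValueError):
    """Raised when a network references unknown species or parameters."""


@dataclass(frozen=True)
class Species:
    """A chemical species in one compartment.

    ``initial_concentration`` is in nM; nuclear species use the
    cytoplasm-volume-relative convention.  ``constant`` marks buffered
    species (e.g. Smad7 held constant in HaCaT) whose derivative is pinned
    to zero.
    """

    name: str
    compartment: str = "cytoplasm"
    initial_concentration: float = 0.0
    constant: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkConfigError(
                f"species {self.name!r}: unknown compartment {self.compartment!r}"
            )
        if self.initial_concentration < 0:
            raise NetworkConfigError(
                f"species {self.name!r}: negative initial concentration"
            )


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction.

    ``reactants`` and ``products`` are species-name tuples (repeats encode
    stoichiometry, e.g. ``("pS2c", "pS2c")`` for homodimerisation).
    ``modifiers`` multiply the rate without being consumed (e.g. Smad7
    driving caveolar LRC degradation, or nuclear Smad complex driving
    induced synthesis).
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: str
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise NetworkConfigError(
                f"reaction {self.name!r}: mass action supports at most 2 reactants"
            )

    @property
    def order(self) -> int:
        return len(self.reactants) + len(self.modifiers)


class ParameterSet(dict):
    """Mapping parameter name -> non-negative value (1/min, 1/(nM min), nM/min).

    Carries an optional provenance tag per parameter
    (``literature`` | ``fixed_prior_model`` | ``estimated``).
    """

    def __init__(self, values: Mapping[str, float] | None = None,
                 provenance: Mapping[str, str] | None = None):
        super().__init__(values or {})
        self.provenance: dict[str, str] = dict(provenance or {})
        for k, v in self.items():
            if v < 0:
                raise NetworkConfigError(f"parameter {k!r} is negative ({v})")

    def copy(self) -> "ParameterSet":
        return ParameterSet(self, self.provenance)

    def updated(self, overrides: Mapping[str, float]) -> "ParameterSet":
        out = self.copy()
        out.update(overrides)
        return out


def mass_action_rate(reaction: Reaction, state: Mapping[str, float],
                     params: Mapping[str, float]) -> float:
    """Instantaneous rate (nM/min) of one reaction at a given state.

    Zeroth-order synthesis reactions return the bare rate constant.
    """
    try:
        rate = params[reaction.rate_constant]
    except KeyError:
        raise NetworkConfigError(
            f"reaction {reaction.name!r}: unknown parameter "
            f"{reaction.rate_constant!r}"
        ) from None
    for name in (*reaction.reactants, *reaction.modifiers):
        try:
            rate *= state[name]
        except KeyError:
            raise NetworkConfigError(
                f"reaction {reaction.name!r}: unknown species {name!r}"
            ) from None
    return rate


@dataclass
class ReactionNetwork:
    """Species + reactions + parameters; builds the ODE right-hand side."""

    name: str
    species: list[Species]
    reactions: list[Reaction]
    parameters: ParameterSet
    volume_ratio: float = 2.3  # V_cyt / V_nuc, used only for rate derivation
    medium_ratio: float = 2000.0  # V_medium / V_cyt, used only for dose conversion
    reaction_sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NetworkConfigError(f"duplicate species names: {dupes}")
        self.index = {n: i for i, n in enumerate(names)}
        self._compiled = None

    # -- structure ---------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_by_name(self, name: str) -> Species:
        return self.species[self.index[name]]

    def stoichiometry_matrix(self) -> np.ndarray:
        """Species x reactions net-stoichiometry matrix."""
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for name in rxn.reactants:
                S[self.index[name], j] -= 1
            for name in rxn.products:
                S[self.index[name], j] += 1
        for i, sp in enumerate(self.species):
            if sp.constant:
                S[i, :] = 0.0
        return S

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def with_parameters(self, overrides: Mapping[str, float]) -> "ReactionNetwork":
        net = replace(self, parameters=self.parameters.updated(overrides))
        net.reaction_sources = dict(self.reaction_sources)
        return net

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return human-readable findings; an empty list means well-formed."""
        findings: list[str] = []
        for sp in self.species:
            if sp.initial_concentration < 0:
                findings.append(f"species {sp.name}: negative initial concentration")
        touched: set[str] = set()
        for rxn in self.reactions:
            if rxn.rate_constant not in self.parameters:
                findings.append(
                    f"reaction {rxn.name}: dangling parameter {rxn.rate_constant!r}"
                )
            for name in (*rxn.reactants, *rxn.products, *rxn.modifiers):
                if name not in self.index:
                    findings.append(
                        f"reaction {rxn.name}: unknown species {name!r}"
                    )
            touched.update(rxn.reactants)
            touched.update(rxn.products)
        for sp in self.species:
            if sp.constant:
                continue
            if sp.name not in touched and sp.initial_concentration == 0:
                findings.append(
                    f"species {sp.name}: never produced nor consumed and starts at 0"
                )
        return findings

    # -- ODE right-hand side ----------------------------------------------

    def _compile(self):
        """Precompute index arrays for a vectorised RHS evaluation."""
        n_rxn = len(self.reactions)
        k = np.empty(n_rxn)
        for j, rxn in enumerate(self.reactions):
            if rxn.rate_constant not in self.parameters:
                raise NetworkConfigError(
                    f"reaction {rxn.name!r}: unknown parameter "
                    f"{rxn.rate_constant!r}"
                )
            k[j] = self.parameters[rxn.rate_constant]
        # factor index lists (reactants + modifiers) grouped by order
        max_order = max((r.order for r in self.reactions), default=0)
        factor_idx = np.zeros((n_rxn, max(max_order, 1)), dtype=np.intp)
        n_factors = np.zeros(n_rxn, dtype=np.intp)
        for j, rxn in enumerate(self.reactions):
            facs = [self.index[n] for n in (*rxn.reactants, *rxn.modifiers)]
            n_factors[j] = len(facs)
            for m, fi in enumerate(facs):
                factor_idx[j, m] = fi
        S = self.stoichiometry_matrix()
        return k, factor_idx, n_factors, S, max_order

    def build_rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Return f(t, y) -> dy/dt for ``scipy.integrate.solve_ivp``.

        Constant (buffered) species have zero derivative.  Nuclear rates are
        already in relative-concentration units, so no volume scaling occurs
        here.
        """
        k, factor_idx, n_factors, S, max_order = self._compile()

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            rates = k.copy()
            for m in range(max_order):
                mask = n_factors > m
                rates[mask] *= y[factor_idx[mask, m]]
            return S @ rates

        return rhs

    def reaction_rates(self, state: np.ndarray) -> np.ndarray:
        """Vector of reaction rates at a state vector (diagnostics)."""
        k, factor_idx, n_factors, S, max_order = self._compile()
        rates = k.copy()
        for m in range(max_order):
            mask = n_factors > m
            rates[mask] *= state[factor_idx[mask, m]]
        return rates


def validate_network(network: ReactionNetwork) -> list[str]:
    """Module-level alias for :meth:`ReactionNetwork.validate`."""
    return network.validate()


# -- declarative reaction strings ------------------------------------------

def reaction_from_string(name: str, text: str) -> Reaction:
    """Parse ``"A + B -> C @ kname [mod1,mod2]"`` into a Reaction.

    An empty left side (``"-> X @ k"``) is a zeroth-order synthesis; an
    empty right side a degradation.  Repeated names encode stoichiometry.
    """
    modifiers: tuple[str, ...] = ()
    if "[" in text:
        text, bracket = text.split("[", 1)
        modifiers = tuple(m.strip() for m in
                          bracket.rstrip("] ").split(",") if m.strip())
    if "@" not in text:
        raise NetworkConfigError(f"reaction {name!r}: missing '@ rate' "
                                 f"in {text!r}")
    arrow_part, rate = text.split("@", 1)
    if "->" not in arrow_part:
        raise NetworkConfigError(f"reaction {name!r}: missing '->' "
                                 f"in {text!r}")
    left, right = arrow_part.split("->", 1)

    def side(s: str) -> tuple[str, ...]:
        return tuple(x.strip() for x in s.split("+") if x.strip())

    return Reaction(name, side(left), side(right), rate.strip(), modifiers)


def reaction_to_string(reaction: Reaction) -> str:
    """Inverse of :func:`reaction_from_string`."""
    left = " + ".join(reaction.reactants)
    right = " + ".join(reaction.products)
    text = f"{left} -> {right} @ {reaction.rate_constant}"
    if reaction.modifiers:
        text += f" [{','.join(reaction.modifiers)}]"
    return text


# -- conserved moieties ----------------------------------------------------

Moiety = Mapping[str, float]  # species name -> stoichiometric weight


def conserved_totals(network: ReactionNetwork,
                     state: np.ndarray | Mapping[str, float],
                     moieties: Mapping[str, Moiety]) -> dict[str, float]:
    """Weighted concentration sums for named moieties (e.g. total Smad2).

    Weights count monomer copies: a Smad2 homomeric complex contributes
    twice per nM of complex.  Nuclear species are in relative units, so the
    sums are directly additive.
    """
    if not isinstance(state, Mapping):
        state = {n: state[i] for n, i in network.index.items()}
    totals: dict[str, float] = {}
    for moiety_name, weights in moieties.items():
        total = 0.0
        for sp_name, w in weights.items():
            if sp_name not in network.index:
                raise NetworkConfigError(
                    f"moiety {moiety_name!r} references unknown species "
                    f"{sp_name!r}"
                )
            total += w * state[sp_name]
        totals[moiety_name] = total
    return totals


def moiety_matrix(network: ReactionNetwork,
                  moieties: Mapping[str, Moiety]) -> np.ndarray:
    """Moieties x species weight matrix (for trajectory-wide sums)."""
    W = np.zeros((len(moieties), len(network.species)))
    for i, weights in enumerate(moieties.values()):
        for sp_name, w in weights.items():
            W[i, network.index[sp_name]] = w
    return W
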