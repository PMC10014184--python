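"""Metabolic network container and constraint-based primitives.

The network is a plain stoichiometric model: metabolites with compartment,
elemental formula and charge; reactions with a sparse stoichiometry, flux
bounds (mmol/gDW/h, arbitrary units) and an optional gene-protein-reaction
(GPR) boolean rule.  Exchange reactions follow the COBRA sign convention:
a single extracellular metabolite with coefficient -1, negative flux =
uptake, positive flux = secretion.

SBML import/export and format validation are delegated to cobrapy; linear
and mixed-integer programs are solved with scipy's HiGHS interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "parse_formula",
    "fba_max",
    "NetworkError",
]

# elemental masses used for stoichiometric-consistency seeding; values are
# only required to be positive, exact isotope masses are irrelevant here
_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class NetworkError(ValueError):
    """Raised for structurally invalid networks or reactions."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string such as ``C6H12O6``.

    Returns an element -> count mapping; an empty string parses to an
    empty mapping (treated as "no annotation" by balance checks).
    """
    if not formula:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for match in _ELEMENT_RE.finditer(formula):
        if match.start() != pos:
            raise NetworkError(f"unparsable formula {formula!r}")
        elem, num = match.group(1), match.group(2)
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(formula):
        raise NetworkError(f"unparsable formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    formula: str = ""
    charge: int = 0

    @property
    def elements(self) -> dict[str, int]:
        return parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0

    @property
    def genes(self) -> set[str]:
        from .gpr import gpr_genes

        return gpr_genes(self.gpr)


@dataclass
class MetabolicNetwork:
    """A stoichiometric model with GPR rules, biomass and exchanges."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    exchange_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return out

    def validate(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._met_index) != len(self.metabolites):
            raise NetworkError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise NetworkError(f"{r.id}: lower bound exceeds upper bound")
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise NetworkError(f"{r.id} references unknown metabolite {met_id}")
        for ex_id in self.exchange_ids:
            rxn = self._rxn_index.get(ex_id)
            if rxn is None:
                raise NetworkError(f"exchange {ex_id} not a reaction")
            if len(rxn.stoichiometry) != 1:
                raise NetworkError(f"exchange {ex_id} must touch exactly one metabolite")
            (met_id,) = rxn.stoichiometry
            if self._met_index[met_id].compartment != "e":
                raise NetworkError(f"exchange {ex_id} metabolite must be extracellular")
        if self.biomass_id not in self._rxn_index:
            raise NetworkError(f"biomass reaction {self.biomass_id} missing")
        if self._rxn_index[self.biomass_id].upper_bound <= 0:
            raise NetworkError("biomass reaction has non-positive upper bound")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions)."""
        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                S[met_pos[met_id], j] = coef
        return S

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            biomass_id=self.biomass_id,
            exchange_ids=set(self.exchange_ids),
        )

    def subnetwork(self, reaction_ids: set[str]) -> "MetabolicNetwork":
        """Restriction to a reaction subset; metabolites are retained."""
        if self.biomass_id not in reaction_ids:
            raise NetworkError("subnetwork must retain the biomass reaction")
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry))
                       for r in self.reactions if r.id in reaction_ids],
            biomass_id=self.biomass_id,
            exchange_ids={e for e in self.exchange_ids if e in reaction_ids},
        )

    # -- medium ------------------------------------------------------------
    def apply_medium(self, medium: dict[str, float]) -> "MetabolicNetwork":
        """Close all exchanges, then open uptakes listed in *medium*.

        *medium* maps exchange reaction id -> maximal uptake rate (>= 0).
        Secretion stays open on every exchange.
        """
        net = self.copy()
        for r in net.reactions:
            if r.id in net.exchange_ids:
                r.lower_bound = -abs(medium.get(r.id, 0.0))
        return net

    # -- SBML via cobrapy --------------------------------------------------
    def to_cobra(self):
        import cobra

        model = cobra.Model("fluxrestore")
        mets = {}
        for m in self.metabolites:
            cm = cobra.Metabolite(m.id, formula=m.formula or None,
                                  charge=m.charge, compartment=m.compartment)
            mets[m.id] = cm
        rxns = []
        for r in self.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
            if r.gpr:
                cr.gene_reaction_rule = r.gpr
            rxns.append(cr)
        model.add_reactions(rxns)
        model.objective = self.biomass_id
        return model

    @classmethod
    def from_cobra(cls, model, biomass_id: str | None = None) -> "MetabolicNetwork":
        mets = [Metabolite(m.id, m.compartment, m.formula or "", int(m.charge or 0))
                for m in model.metabolites]
        rxns = [Reaction(r.id, {m.id: c for m, c in r.metabolites.items()},
                         r.lower_bound, r.upper_bound, r.gene_reaction_rule or "")
                for r in model.reactions]
        exchange_ids = {r.id for r in model.reactions
                        if len(r.metabolites) == 1
                        and next(iter(r.metabolites)).compartment == "e"}
        if biomass_id is None:
            cand = [r.id for r in model.reactions if "biomass" in r.id.lower()]
            if not cand:
                raise NetworkError("cannot infer biomass reaction id")
            biomass_id = cand[0]
        return cls(mets, rxns, biomass_id, exchange_ids)

    def write_sbml(self, path: str) -> None:
        import cobra.io

        cobra.io.write_sbml_model(self.to_cobra(), path)

    @classmethod
    def read_sbml(cls, path: str, biomass_id: str | None = None) -> "MetabolicNetwork":
        import cobra.io

        return cls.from_cobra(cobra.io.read_sbml_model(path), biomass_id)


def fba_max(network: MetabolicNetwork, objective_id: str,
            sense: float = 1.0) -> tuple[float, dict[str, float] | None]:
    """Maximize (sense=1) or minimize (sense=-1) one reaction's flux.

    Returns ``(optimum, flux_dict)``; ``(nan, None)`` if infeasible.
    """
    S = network.stoichiometric_matrix()
    n = len(network.reactions)
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    c = np.zeros(n)
    c[network.reaction_ids.index(objective_id)] = -sense  # linprog minimizes
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    if not res.success:
        return float("nan"), None
    flux = dict(zip(network.reaction_ids, res.x))
    return sense * -res.fun, flux
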