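"""Expression-driven context-specific model extraction, gap-filling and QC.

Per sample, reactions of the generic network are scored from protein
abundance through the GPR rules, and a context-specific submodel is
selected by maximizing the summed evidence weight of the included
reactions subject to every included internal reaction being active in a
common steady-state flux distribution that sustains biomass formation
(tINIT-style selection).  A minimum-cardinality gap-fill against the
parent network guarantees in-silico growth, and MEMOTE-style quality
metrics (stoichiometric consistency, mass/charge balance, metabolite
connectivity) are reported per model.

Exact selection and gap-filling are mixed-integer linear programs solved
with HiGHS; a greedy prune-based fallback is provided for networks too
large for the exact mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .gpr import evaluate_gpr
from .network import MetabolicNetwork, fba_max

__all__ = [
    "ReactionScores",
    "ContextModel",
    "ModelQC",
    "score_reactions",
    "extract_context",
    "gapfill_growth",
    "qc_model",
    "model_stats",
    "ExtractionError",
]

#: binary-variable count above which the exact MILP falls back to greedy
EXACT_MILP_LIMIT = 1000


class ExtractionError(RuntimeError):
    pass


@dataclass
class ReactionScores:
    """Per-reaction evidence weights derived from one sample's proteome.

    ``weights`` maps reaction id -> signed weight; ``provenance`` maps
    reaction id -> mapped expression value, or ``None`` for reactions
    without a GPR (which receive a small negative default weight) and
    for exchange/biomass pseudo-reactions (weight 0).
    """

    weights: dict[str, float]
    provenance: dict[str, float | None]
    threshold: float


@dataclass
class ContextModel:
    """A per-sample reaction subset of a parent network."""

    parent: MetabolicNetwork
    kept_reactions: set[str]
    gapfilled_reactions: set[str]
    medium: dict[str, float]
    sample_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.kept_reactions & self.gapfilled_reactions:
            raise ValueError("kept and gap-filled sets must be disjoint")
        unknown = (self.kept_reactions | self.gapfilled_reactions) - set(self.parent.reaction_ids)
        if unknown:
            raise ValueError(f"unknown reactions {sorted(unknown)}")

    @property
    def reaction_ids(self) -> set[str]:
        return self.kept_reactions | self.gapfilled_reactions

    @property
    def metabolite_ids(self) -> set[str]:
        """Compartment-qualified metabolites touched by included reactions."""
        out: set[str] = set()
        for rid in self.reaction_ids:
            out |= set(self.parent.reaction(rid).stoichiometry)
        return out

    def network(self) -> MetabolicNetwork:
        """Materialize the submodel with the medium applied."""
        return self.parent.apply_medium(self.medium).subnetwork(self.reaction_ids)

    def grows(self, v_min: float = 1e-3) -> bool:
        mu, _ = fba_max(self.network(), self.parent.biomass_id)
        return math.isfinite(mu) and mu >= v_min - 1e-9


@dataclass
class ModelQC:
    stoichiometric_consistency: float
    mass_balanced_fraction: float
    charge_balanced_fraction: float
    metabolite_connectivity_fraction: float


# --------------------------------------------------------------------------
# reaction scoring
# --------------------------------------------------------------------------

def score_reactions(network: MetabolicNetwork, expression: dict[str, float],
                    threshold: float | None = None, w_max: float = 5.0,
                    no_gpr_weight: float = -0.1) -> ReactionScores:
    """Map gene abundances to signed reaction evidence weights.

    GPR rules are evaluated with AND = min, OR = sum; the mapped
    expression ``e_j`` becomes ``w_j = clip(ln(e_j / threshold), +-w_max)``.
    The default threshold is the median mapped expression over the
    sample's GPR-bearing reactions, so roughly half the scored reactions
    carry positive evidence.  Reactions without a GPR get the small
    negative ``no_gpr_weight``; exchanges and biomass get weight zero.
    """
    if threshold is not None and threshold <= 0:
        raise ValueError("threshold must be positive")
    if not (set(expression) & network.genes):
        raise ValueError("expression covers no gene of the network")
    neutral = network.exchange_ids | {network.biomass_id}
    mapped: dict[str, float | None] = {}
    for r in network.reactions:
        if r.id in neutral:
            mapped[r.id] = None
        else:
            mapped[r.id] = evaluate_gpr(r.gpr, expression)
    if threshold is None:
        scored = [v for v in mapped.values() if v is not None]
        threshold = float(np.median(scored))
        if threshold <= 0:
            raise ValueError("median reaction expression is non-positive")
    weights: dict[str, float] = {}
    for r in network.reactions:
        e = mapped[r.id]
        if r.id in neutral:
            weights[r.id] = 0.0
        elif e is None:
            weights[r.id] = no_gpr_weight
        elif e <= 0:
            weights[r.id] = -w_max
        else:
            weights[r.id] = float(np.clip(np.log(e / threshold), -w_max, w_max))
    return ReactionScores(weights, mapped, threshold)


# --------------------------------------------------------------------------
# context extraction
# --------------------------------------------------------------------------

def _split_bounds(network: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    ub_fwd = np.array([max(0.0, r.upper_bound) for r in network.reactions])
    ub_rev = np.array([max(0.0, -r.lower_bound) for r in network.reactions])
    return ub_fwd, ub_rev


def flux_capacities(network: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Attainable forward/reverse flux per reaction (FVA on the full network).

    These tighten the big-M coefficients of the selection and gap-fill
    MILPs: with raw bounds as big-M a solver may leave a binary at its
    integrality tolerance and smuggle big-M * tolerance of flux through a
    nominally excluded reaction.  The medium-limited capacities are
    orders of magnitude smaller, closing that hole.
    """
    S = network.stoichiometric_matrix()
    n = len(network.reactions)
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    cap_fwd = np.zeros(n)
    cap_rev = np.zeros(n)
    for j in range(n):
        for sense, cap in ((-1.0, cap_fwd), (1.0, cap_rev)):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb, ub]), method="highs")
            if res.success:
                # fwd: min -v_j => max v_j = -fun; rev: min v_j => -fun
                cap[j] = max(0.0, -res.fun)
    margin = 1e-6
    return (np.minimum(cap_fwd * (1 + 1e-6) + margin, np.maximum(ub, 0.0)),
            np.minimum(cap_rev * (1 + 1e-6) + margin, np.maximum(-lb, 0.0)))


def _extract_exact(network: MetabolicNetwork, weights: dict[str, float],
                   v_min: float, delta: float,
                   caps: tuple[np.ndarray, np.ndarray] | None = None) -> set[str]:
    """tINIT-style MILP: max sum(w_j y_j) with simultaneous activation.

    Variables: split fluxes v+ / v- per reaction and one binary y per
    internal reaction; included reactions must carry total split flux
    >= delta in a single steady-state distribution with biomass >= v_min.
    """
    rxn_ids = network.reaction_ids
    n = len(rxn_ids)
    neutral = network.exchange_ids | {network.biomass_id}
    internal = [i for i, rid in enumerate(rxn_ids) if rid not in neutral]
    k = len(internal)
    S = network.stoichiometric_matrix()
    ub_fwd, ub_rev = caps if caps is not None else flux_capacities(network)

    nv = 2 * n + k
    c = np.zeros(nv)
    for t, i in enumerate(internal):
        c[2 * n + t] = -weights[rxn_ids[i]]  # milp minimizes

    rows, lo, hi = [], [], []
    # steady state: S (v+ - v-) = 0
    A_ss = np.hstack([S, -S, np.zeros((S.shape[0], k))])
    rows.append(A_ss)
    lo.extend([0.0] * S.shape[0])
    hi.extend([0.0] * S.shape[0])
    # coupling and activation per internal reaction
    A_cpl = np.zeros((3 * k, nv))
    for t, i in enumerate(internal):
        A_cpl[3 * t, i] = 1.0
        A_cpl[3 * t, 2 * n + t] = -ub_fwd[i]
        A_cpl[3 * t + 1, n + i] = 1.0
        A_cpl[3 * t + 1, 2 * n + t] = -ub_rev[i]
        A_cpl[3 * t + 2, i] = 1.0
        A_cpl[3 * t + 2, n + i] = 1.0
        A_cpl[3 * t + 2, 2 * n + t] = -delta
        lo.extend([-np.inf, -np.inf, 0.0])
        hi.extend([0.0, 0.0, np.inf])
    rows.append(A_cpl)
    A = np.vstack(rows)

    lb_v = np.zeros(nv)
    ub_v = np.concatenate([ub_fwd, ub_rev, np.ones(k)])
    i_bio = rxn_ids.index(network.biomass_id)
    lb_v[i_bio] = v_min  # biomass task
    integrality = np.zeros(nv)
    integrality[2 * n:] = 1

    res = milp(c=c, constraints=LinearConstraint(A, lo, hi),
               bounds=Bounds(lb_v, ub_v), integrality=integrality)
    if not res.success:
        raise ExtractionError(f"extraction MILP infeasible: {res.message}")
    y = res.x[2 * n:]
    kept = {rid for rid in neutral}
    kept |= {rxn_ids[i] for t, i in enumerate(internal) if y[t] > 0.5}
    return kept


def _extract_greedy(network: MetabolicNetwork, weights: dict[str, float],
                    v_min: float, delta: float) -> set[str]:
    """Greedy prune: drop negative-evidence reactions that are not needed
    for growth, then remove reactions left unable to carry flux."""
    biomass = network.biomass_id
    neutral = network.exchange_ids | {biomass}
    kept = set(network.reaction_ids)
    negatives = sorted((rid for rid in kept - neutral if weights[rid] < 0),
                       key=lambda rid: weights[rid])
    for rid in negatives:
        trial = network.subnetwork(kept - {rid})
        mu, _ = fba_max(trial, biomass)
        if math.isfinite(mu) and mu >= v_min - 1e-9:
            kept.remove(rid)
    # flux-consistency cleanup: drop internal reactions with no capacity
    changed = True
    while changed:
        changed = False
        sub = network.subnetwork(kept)
        for rid in sorted(kept - neutral):
            cap = _max_abs_flux(sub, rid, biomass, v_min)
            if cap < delta - 1e-12:
                kept.remove(rid)
                changed = True
        if changed:
            continue
    return kept


def _max_abs_flux(network: MetabolicNetwork, rxn_id: str,
                  biomass_id: str, v_min: float) -> float:
    """Maximal |v| of one reaction subject to growth (FVA-style)."""
    S = network.stoichiometric_matrix()
    n = len(network.reactions)
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    lb[network.reaction_ids.index(biomass_id)] = max(
        lb[network.reaction_ids.index(biomass_id)], v_min)
    j = network.reaction_ids.index(rxn_id)
    best = 0.0
    for sense in (+1.0, -1.0):
        c = np.zeros(n)
        c[j] = -sense
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.success:
            best = max(best, abs(sense * -res.fun))
    return best


def extract_context(network: MetabolicNetwork, scores: ReactionScores,
                    medium: dict[str, float], v_min: float = 1e-3,
                    delta: float = 1e-3, mode: str = "exact",
                    sample_id: str = "", group: str = "",
                    flux_caps: tuple[np.ndarray, np.ndarray] | None = None) -> ContextModel:
    """Select the evidence-maximal growing submodel for one sample.

    ``mode='exact'`` solves the selection MILP (falls back to greedy with
    a warning above :data:`EXACT_MILP_LIMIT` binaries); ``mode='greedy'``
    prunes negative-evidence reactions while preserving growth.
    Exchanges and the biomass reaction are always retained.
    """
    missing = set(network.reaction_ids) - set(scores.weights)
    if missing:
        raise ValueError(f"scores missing for reactions {sorted(missing)}")
    bounded = network.apply_medium(medium)
    mu, _ = fba_max(bounded, network.biomass_id)
    if not (math.isfinite(mu) and mu >= v_min - 1e-9):
        raise ExtractionError("biomass task infeasible on the full network")
    n_internal = len(set(network.reaction_ids) - network.exchange_ids) - 1
    if mode == "exact" and n_internal > EXACT_MILP_LIMIT:
        warnings.warn(f"{n_internal} binaries exceed the exact-MILP limit; "
                      "falling back to greedy extraction", stacklevel=2)
        mode = "greedy"
    if mode == "exact":
        kept = _extract_exact(bounded, scores.weights, v_min, delta, caps=flux_caps)
    elif mode == "greedy":
        kept = _extract_greedy(bounded, scores.weights, v_min, delta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ContextModel(parent=network, kept_reactions=kept,
                        gapfilled_reactions=set(), medium=dict(medium),
                        sample_id=sample_id, group=group)


# --------------------------------------------------------------------------
# gap-filling
# --------------------------------------------------------------------------

def gapfill_growth(context: ContextModel, v_min: float = 1e-3,
                   flux_caps: tuple[np.ndarray, np.ndarray] | None = None) -> ContextModel:
    """Add a minimum-cardinality set of parent reactions so the model grows.

    Solved exactly as a MILP over the candidate set (parent reactions not
    in the context).  A context that already grows is returned with an
    unchanged (typically empty) gap-fill set.
    """
    parent = context.parent.apply_medium(context.medium)
    if context.grows(v_min):
        return context
    rxn_ids = parent.reaction_ids
    n = len(rxn_ids)
    included = context.reaction_ids
    candidates = [i for i, rid in enumerate(rxn_ids) if rid not in included]
    k = len(candidates)
    S = parent.stoichiometric_matrix()
    ub_fwd, ub_rev = flux_caps if flux_caps is not None else flux_capacities(parent)

    nv = 2 * n + k
    c = np.zeros(nv)
    c[2 * n:] = 1.0  # minimize number of additions

    A_ss = np.hstack([S, -S, np.zeros((S.shape[0], k))])
    lo = [0.0] * S.shape[0]
    hi = [0.0] * S.shape[0]
    A_cpl = np.zeros((2 * k, nv))
    for t, i in enumerate(candidates):
        A_cpl[2 * t, i] = 1.0
        A_cpl[2 * t, 2 * n + t] = -ub_fwd[i]
        A_cpl[2 * t + 1, n + i] = 1.0
        A_cpl[2 * t + 1, 2 * n + t] = -ub_rev[i]
        lo.extend([-np.inf, -np.inf])
        hi.extend([0.0, 0.0])
    A = np.vstack([A_ss, A_cpl])

    lb_v = np.zeros(nv)
    ub_v = np.concatenate([ub_fwd, ub_rev, np.ones(k)])
    i_bio = rxn_ids.index(parent.biomass_id)
    lb_v[i_bio] = v_min
    integrality = np.zeros(nv)
    integrality[2 * n:] = 1
    res = milp(c=c, constraints=LinearConstraint(A, lo, hi),
               bounds=Bounds(lb_v, ub_v), integrality=integrality)
    if not res.success:
        raise ExtractionError("gap-filling infeasible: biomass unreachable "
                              "even with all parent reactions")
    added = {rxn_ids[i] for t, i in enumerate(candidates) if res.x[2 * n + t] > 0.5}
    return ContextModel(parent=context.parent,
                        kept_reactions=set(context.kept_reactions),
                        gapfilled_reactions=set(context.gapfilled_reactions) | added,
                        medium=dict(context.medium),
                        sample_id=context.sample_id, group=context.group)


# --------------------------------------------------------------------------
# MEMOTE-style quality metrics
# --------------------------------------------------------------------------

def _pseudo_reactions(network: MetabolicNetwork) -> set[str]:
    return network.exchange_ids | {network.biomass_id}


def qc_model(model: ContextModel | MetabolicNetwork) -> ModelQC:
    """Stoichiometric consistency, mass/charge balance and connectivity.

    Exchange and biomass pseudo-reactions are exempt from balance and
    consistency checks (they are net drains by design).  Balance
    fractions are computed over reactions whose metabolites all carry
    formula/charge annotation; missing annotation shrinks the
    denominator with a warning.
    """
    network = model.network() if isinstance(model, ContextModel) else model
    pseudo = _pseudo_reactions(network)
    internal = [r for r in network.reactions if r.id not in pseudo]

    # stoichiometric consistency: find a strictly positive metabolite mass
    # vector m with S_int^T m = 0; the maximal consistent subset is read
    # off an LP maximizing sum(k), 0 <= k <= 1, k <= m (Gevorgyan-style)
    active_mets = sorted({m for r in internal for m in r.stoichiometry})
    if internal and active_mets:
        met_pos = {m: i for i, m in enumerate(active_mets)}
        St = np.zeros((len(internal), len(active_mets)))
        for i, r in enumerate(internal):
            for met_id, coef in r.stoichiometry.items():
                St[i, met_pos[met_id]] = coef
        nm = len(active_mets)
        # variables: m (nm), k (nm)
        c = np.concatenate([np.zeros(nm), -np.ones(nm)])
        A_eq = np.hstack([St, np.zeros_like(St)])
        A_ub = np.hstack([-np.eye(nm), np.eye(nm)])  # k - m <= 0
        bounds = [(0, 1e6)] * nm + [(0, 1)] * nm
        res = linprog(c, A_ub=A_ub, b_ub=np.zeros(nm), A_eq=A_eq,
                      b_eq=np.zeros(len(internal)), bounds=bounds, method="highs")
        if res.success:
            consistent = int(np.sum(res.x[:nm] > 1e-6))
            stoich_consistency = consistent / nm
        else:
            stoich_consistency = 0.0
    else:
        stoich_consistency = 1.0

    mass_ok = mass_total = charge_ok = charge_total = 0
    for r in internal:
        mets = [network.metabolite(m) for m in r.stoichiometry]
        if all(m.formula for m in mets):
            mass_total += 1
            residual: dict[str, float] = {}
            for m in mets:
                for elem, cnt in m.elements.items():
                    residual[elem] = residual.get(elem, 0.0) + r.stoichiometry[m.id] * cnt
            if all(abs(v) < 1e-6 for v in residual.values()):
                mass_ok += 1
        charge_total += 1
        q = sum(r.stoichiometry[m.id] * m.charge for m in mets)
        if abs(q) < 1e-6:
            charge_ok += 1
    if internal and mass_total < len(internal):
        warnings.warn(f"only {mass_total}/{len(internal)} reactions fully "
                      "formula-annotated; mass balance reported over that subset",
                      stacklevel=2)

    used = {m for r in network.reactions for m in r.stoichiometry}
    connectivity = len(used) / len(network.metabolites) if network.metabolites else 1.0
    return ModelQC(
        stoichiometric_consistency=stoich_consistency,
        mass_balanced_fraction=mass_ok / mass_total if mass_total else 1.0,
        charge_balanced_fraction=charge_ok / charge_total if charge_total else 1.0,
        metabolite_connectivity_fraction=connectivity,
    )


# --------------------------------------------------------------------------
# model-content statistics
# --------------------------------------------------------------------------

def model_stats(models: list[ContextModel]) -> dict:
    """Per-group mean reaction/metabolite counts and 7-region Venn counts.

    Metabolite identity is compartment-qualified: the same chemical
    species in cytosol and mitochondria counts as two metabolites.
    """
    from .proteome_stats import presence_venn

    groups = sorted({m.group for m in models})
    mean_counts = {}
    rxn_union: dict[str, set[str]] = {g: set() for g in groups}
    met_union: dict[str, set[str]] = {g: set() for g in groups}
    for g in groups:
        members = [m for m in models if m.group == g]
        mean_counts[g] = {
            "reactions": float(np.mean([len(m.reaction_ids) for m in members])),
            "metabolites": float(np.mean([len(m.metabolite_ids) for m in members])),
        }
        for m in members:
            rxn_union[g] |= m.reaction_ids
            met_union[g] |= m.metabolite_ids
    out = {"mean_counts": mean_counts}
    if len(groups) == 3:
        out["reaction_venn"] = presence_venn(rxn_union)
        out["metabolite_venn"] = presence_venn(met_union)
    return out
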