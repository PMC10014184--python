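"""Least-absolute-deviation flux estimation and flux-sum profiling.

For each context model a steady-state flux distribution is estimated by
minimizing the summed absolute deviation between fluxes and
expression-derived target values (LAD), subject to mass balance, bounds,
the medium and a minimal biomass flux.  The per-metabolite flux-sum

    Phi_i = sum_j max(S_ij * v_j, 0)

— the total production rate of metabolite i, equal to half its total
absolute turnover at steady state — summarises the metabolite's overall
importance in the flux state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gpr import evaluate_gpr
from .model_extraction import ContextModel

__all__ = [
    "FluxState",
    "expression_targets",
    "lad_fit",
    "flux_sum",
    "SteadyStateError",
]

STEADY_STATE_TOL = 1e-6


class SteadyStateError(RuntimeError):
    pass


@dataclass
class FluxState:
    """Optimal fluxes of one context model."""

    fluxes: pd.Series          # reaction id -> flux
    objective_value: float     # sum of absolute deviations at the optimum
    solver_status: str

    def __getitem__(self, rxn_id: str) -> float:
        return float(self.fluxes[rxn_id])


def expression_targets(context: ContextModel,
                       expression: dict[str, float]) -> dict[str, float]:
    """Expression-scaled flux targets for GPR-bearing internal reactions.

    The mapped reaction expression ``e_j`` (AND = min, OR = sum) is
    scaled linearly so the most-expressed reaction targets its upper
    bound: ``d_j = ub_j * e_j / max_k e_k``.  Exchanges, biomass and
    GPR-less reactions carry no target and stay out of the objective.
    """
    net = context.network()
    pseudo = net.exchange_ids | {net.biomass_id}
    mapped = {}
    for r in net.reactions:
        if r.id in pseudo or not r.gpr:
            continue
        e = evaluate_gpr(r.gpr, expression)
        if e is not None:
            mapped[r.id] = max(0.0, e)
    if not mapped or max(mapped.values()) <= 0:
        raise ValueError("no positive reaction-level expression to derive targets")
    e_max = max(mapped.values())
    return {rid: net.reaction(rid).upper_bound * e / e_max
            for rid, e in mapped.items()}


def lad_fit(context: ContextModel, targets: dict[str, float],
            v_min: float = 1e-3) -> FluxState:
    """Minimize sum_j |v_j - d_j| over steady-state flux distributions.

    Linear program with split deviation variables: for every targeted
    reaction t, v_t - d_t = p_t - q_t with p, q >= 0 and objective
    sum(p + q); constraints are S v = 0, flux bounds, the medium (already
    part of the context) and biomass >= v_min.
    """
    net = context.network()
    rxn_ids = net.reaction_ids
    unknown = set(targets) - set(rxn_ids)
    if unknown:
        raise ValueError(f"targets for reactions not in the model: {sorted(unknown)}")
    n = len(rxn_ids)
    tgt = sorted(targets)
    k = len(tgt)
    S = net.stoichiometric_matrix()

    # variables: v (n, signed) then p, q (k each)
    c = np.concatenate([np.zeros(n), np.ones(2 * k)])
    A_eq = np.zeros((S.shape[0] + k, n + 2 * k))
    b_eq = np.zeros(S.shape[0] + k)
    A_eq[:S.shape[0], :n] = S
    for t, rid in enumerate(tgt):
        j = rxn_ids.index(rid)
        A_eq[S.shape[0] + t, j] = 1.0
        A_eq[S.shape[0] + t, n + t] = -1.0
        A_eq[S.shape[0] + t, n + k + t] = 1.0
        b_eq[S.shape[0] + t] = targets[rid]
    lb = np.concatenate([[r.lower_bound for r in net.reactions], np.zeros(2 * k)])
    ub = np.concatenate([[r.upper_bound for r in net.reactions], np.full(2 * k, np.inf)])
    i_bio = rxn_ids.index(net.biomass_id)
    lb[i_bio] = max(lb[i_bio], v_min)

    res = linprog(c, A_eq=A_eq, b_eq=b_eq,
                  bounds=np.column_stack([lb, ub]), method="highs")
    if not res.success:
        raise SteadyStateError(f"LAD LP failed: {res.message}")
    v = res.x[:n]
    residual = float(np.abs(S @ v).max())
    if residual > STEADY_STATE_TOL:
        raise SteadyStateError(f"steady-state residual {residual:.2e} above tolerance")
    return FluxState(pd.Series(v, index=rxn_ids, name=context.sample_id or "flux"),
                     float(res.fun), "optimal")


def flux_sum(context: ContextModel, flux: FluxState) -> pd.Series:
    """Per-metabolite flux-sum Phi_i of a steady-state flux distribution.

    Phi_i is the summed production of metabolite i; at steady state it
    equals the summed consumption and half the total absolute turnover.
    Metabolites of the context without any flux have Phi = 0.
    """
    net = context.network()
    S = net.stoichiometric_matrix()
    v = flux.fluxes.reindex(net.reaction_ids).to_numpy()
    if np.isnan(v).any():
        raise ValueError("flux state does not cover the context model")
    residual = float(np.abs(S @ v).max())
    if residual > STEADY_STATE_TOL:
        raise SteadyStateError(f"flux is not at steady state (residual {residual:.2e})")
    phi = np.maximum(S * v[None, :], 0.0).sum(axis=1)
    return pd.Series(phi, index=net.metabolite_ids, name=flux.fluxes.name)
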