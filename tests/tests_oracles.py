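"""Shared brute-force oracles: exhaustive-enumeration optima for context
extraction and gap-filling on a small two-route network.

Used by the unit tests and by the acceptance script; independent of the
MILP code paths they check (plain LP feasibility per enumerated subset).
"""

import itertools

import numpy as np
from scipy.optimize import linprog

from fluxrestore.model_extraction import (ContextModel, ReactionScores,
                                          extract_context, gapfill_growth)
from fluxrestore.network import MetabolicNetwork, Metabolite, Reaction

V_MIN = 1e-3
DELTA = 1e-3


def mini_network() -> MetabolicNetwork:
    """Two routes from one substrate to biomass plus a reversible cross
    link; 6 internal reactions, small enough for subset enumeration."""
    mets = [Metabolite("a_e", "e"), Metabolite("a_c", "c"),
            Metabolite("b_c", "c"), Metabolite("c_c", "c"),
            Metabolite("bm_c", "c")]
    rxns = [
        Reaction("EX_a", {"a_e": -1}, -10, 1000),
        Reaction("T1", {"a_e": -1, "a_c": 1}, 0, 1000),
        Reaction("R1", {"a_c": -1, "b_c": 1}, 0, 1000),
        Reaction("R2", {"b_c": -1, "bm_c": 1}, 0, 1000),
        Reaction("R3", {"a_c": -1, "c_c": 1}, 0, 1000),
        Reaction("R4", {"c_c": -1, "bm_c": 1}, 0, 1000),
        Reaction("R5", {"b_c": -1, "c_c": 1}, -1000, 1000),
        Reaction("BIOMASS", {"bm_c": -1}, 0, 1000),
    ]
    return MetabolicNetwork(mets, rxns, "BIOMASS", {"EX_a"})


def subset_feasible(network: MetabolicNetwork, kept_internal: set,
                    all_internal: set, v_min: float = V_MIN,
                    delta: float = DELTA) -> bool:
    """LP check: one steady-state v with biomass >= v_min in which every
    kept internal reaction carries total split flux >= delta."""
    ids = network.reaction_ids
    n = len(ids)
    S = network.stoichiometric_matrix()
    ub_f = np.array([max(0.0, r.upper_bound) for r in network.reactions])
    ub_r = np.array([max(0.0, -r.lower_bound) for r in network.reactions])
    for i, rid in enumerate(ids):
        if rid in all_internal and rid not in kept_internal:
            ub_f[i] = ub_r[i] = 0.0
    A_eq = np.hstack([S, -S])
    rows, b = [], []
    for i, rid in enumerate(ids):
        if rid in kept_internal:
            row = np.zeros(2 * n)
            row[i] = row[n + i] = -1.0
            rows.append(row)
            b.append(-delta)
    lb = np.zeros(2 * n)
    lb[ids.index("BIOMASS")] = v_min
    res = linprog(np.zeros(2 * n),
                  A_ub=np.vstack(rows) if rows else None,
                  b_ub=np.array(b) if rows else None,
                  A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, np.concatenate([ub_f, ub_r])]),
                  method="highs")
    return res.success


def extraction_matches_enumeration(n_trials: int = 5, seed: int = 9) -> bool:
    """MILP extraction equals the exhaustive-enumeration optimum on the
    mini network for random generic weights."""
    net = mini_network()
    medium = {"EX_a": 10.0}
    bounded = net.apply_medium(medium)
    internal = [rid for rid in net.reaction_ids
                if rid not in net.exchange_ids and rid != "BIOMASS"]
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        weights = dict.fromkeys(net.reaction_ids, 0.0)
        for rid in internal:
            weights[rid] = float(rng.normal(0, 1))
        best_obj, best_sets = -np.inf, []
        for r in range(len(internal) + 1):
            for kept in itertools.combinations(internal, r):
                if subset_feasible(bounded, set(kept), set(internal)):
                    obj = sum(weights[k] for k in kept)
                    if obj > best_obj + 1e-12:
                        best_obj, best_sets = obj, [set(kept)]
                    elif abs(obj - best_obj) <= 1e-12:
                        best_sets.append(set(kept))
        scores = ReactionScores(weights, dict.fromkeys(weights), 1.0)
        ctx = extract_context(net, scores, medium)
        kept_internal = ctx.kept_reactions & set(internal)
        if kept_internal not in best_sets:
            return False
        if abs(sum(weights[k] for k in kept_internal) - best_obj) > 1e-9:
            return False
    return True


def gapfill_matches_enumeration() -> bool:
    """Gap-fill addition-set size equals the brute-force minimum over all
    candidate subsets on the mini network."""
    net = mini_network()
    medium = {"EX_a": 10.0}
    kept = {"EX_a", "BIOMASS", "R5"}
    ctx = ContextModel(net, kept, set(), medium)
    filled = gapfill_growth(ctx)
    if not filled.grows():
        return False
    candidates = sorted(set(net.reaction_ids) - kept)
    for r in range(len(candidates) + 1):
        for added in itertools.combinations(candidates, r):
            if ContextModel(net, kept, set(added), medium).grows():
                return len(filled.gapfilled_reactions) == r
    return False
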