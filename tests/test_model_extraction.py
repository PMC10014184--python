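"""Context extraction, gap-filling and model QC against exhaustive oracles."""

import math

import numpy as np
import pytest
from fluxrestore.model_extraction import (ContextModel, ExtractionError,
                                          ReactionScores, extract_context,
                                          gapfill_growth, model_stats, qc_model,
                                          score_reactions)
from fluxrestore.network import Reaction
from fluxrestore.synthetic_data import fatty_acid_branch_reactions
from tests_oracles import extraction_matches_enumeration



# -- scoring ---------------------------------------------------------------

def test_score_or_rule_closed_form(toy_network):
    tau = 100.0
    expr = {g: 0.0 for g in toy_network.genes}
    expr.update({"Facl1": 2 * tau, "Facl2": 0.0, "Facl3": 0.0})
    scores = score_reactions(toy_network, expr, threshold=tau)
    assert scores.weights["FACOAL"] == pytest.approx(math.log(2))


def test_score_and_rule_at_threshold(toy_network):
    tau = 50.0
    expr = dict.fromkeys(toy_network.genes, tau)
    scores = score_reactions(toy_network, expr, threshold=tau)
    assert scores.weights["ECH1"] == pytest.approx(0.0)  # min(tau, tau) = tau


def test_score_conventions(toy_network, proteome_truth):
    proteome, _ = proteome_truth
    expr = proteome.sample_expression(proteome.samples[0])
    scores = score_reactions(toy_network, expr, w_max=5.0)
    from fluxrestore.gpr import evaluate_gpr

    for r in toy_network.reactions:
        w = scores.weights[r.id]
        assert abs(w) <= 5.0
        if r.id in toy_network.exchange_ids or r.id == "BIOMASS":
            assert w == 0.0
        elif not r.gpr:
            assert w == pytest.approx(-0.1)
        else:
            e = evaluate_gpr(r.gpr, expr)
            assert w == pytest.approx(
                np.clip(np.log(e / scores.threshold), -5, 5))


def test_score_invalid_threshold(toy_network):
    with pytest.raises(ValueError, match="threshold"):
        score_reactions(toy_network, dict.fromkeys(toy_network.genes, 1.0),
                        threshold=0.0)


# -- extraction ------------------------------------------------------------

def _scores_from(network, weights):
    return ReactionScores(weights, dict.fromkeys(weights), 1.0)


def test_all_positive_weights_keep_everything(toy_network, medium):
    weights = {rid: 1.0 for rid in toy_network.reaction_ids}
    for rid in toy_network.exchange_ids | {"BIOMASS"}:
        weights[rid] = 0.0
    ctx = extract_context(toy_network, _scores_from(toy_network, weights), medium)
    assert ctx.kept_reactions == set(toy_network.reaction_ids)


def test_planted_design_recovers_branch(study):
    """Disease-group models contain the fatty-acid branch; control models
    exclude at least one of its reactions (planted evidence pattern)."""
    branch = fatty_acid_branch_reactions(study.network)
    for sample, ctx in study.models.items():
        if ctx.group == "AD_VEH":
            assert branch <= ctx.reaction_ids, sample
        elif ctx.group == "WT_VEH":
            assert len(branch - ctx.reaction_ids) >= 1, sample


def test_exact_and_greedy_agree_on_separable_fixture(toy_network, medium,
                                                     proteome_truth):
    proteome, _ = proteome_truth
    for sample in ("WT_VEH_1", "AD_VEH_1"):
        scores = score_reactions(toy_network, proteome.sample_expression(sample))
        exact = extract_context(toy_network, scores, medium, mode="exact")
        greedy = extract_context(toy_network, scores, medium, mode="greedy")
        branch = fatty_acid_branch_reactions(toy_network)
        assert (branch <= exact.kept_reactions) == (branch <= greedy.kept_reactions)


def test_extraction_matches_exhaustive_enumeration():
    """MILP selection equals subset-enumeration optima for random generic
    weights on the 6-internal-reaction two-route network."""
    assert extraction_matches_enumeration(n_trials=5)


def test_extraction_infeasible_task(toy_network):
    weights = dict.fromkeys(toy_network.reaction_ids, 1.0)
    with pytest.raises(ExtractionError, match="infeasible"):
        extract_context(toy_network, _scores_from(toy_network, weights), medium={})


# -- gap-filling -----------------------------------------------------------

def test_gapfill_noop_when_growing(study):
    for ctx in study.models.values():
        again = gapfill_growth(ctx)
        assert again.gapfilled_reactions == ctx.gapfilled_reactions
        assert again.grows()


def test_gapfill_restores_single_essential_reaction(toy_network, medium):
    # GLCt is essential once the fatty-acid branch is removed
    branch = fatty_acid_branch_reactions(toy_network)
    kept = set(toy_network.reaction_ids) - branch - {"GLCt"}
    ctx = ContextModel(toy_network, kept, set(), medium)
    assert not ctx.grows()
    filled = gapfill_growth(ctx)
    assert filled.gapfilled_reactions == {"GLCt"}
    assert filled.grows()


def test_gapfill_minimality_vs_exhaustive():
    from tests_oracles import gapfill_matches_enumeration

    assert gapfill_matches_enumeration()


def test_gapfill_idempotent(toy_network, medium):
    kept = set(toy_network.reaction_ids) - {"GLCt", "FAt"}
    ctx = ContextModel(toy_network, kept, set(), medium)
    once = gapfill_growth(ctx)
    twice = gapfill_growth(once)
    assert twice.gapfilled_reactions == once.gapfilled_reactions


# -- QC --------------------------------------------------------------------

def test_qc_pristine_network_all_ones(toy_network):
    qc = qc_model(toy_network)
    assert qc.stoichiometric_consistency == 1.0
    assert qc.mass_balanced_fraction == 1.0
    assert qc.charge_balanced_fraction == 1.0
    assert qc.metabolite_connectivity_fraction == 1.0


def test_qc_detects_injected_mass_imbalance(toy_network):
    broken = toy_network.copy()
    broken.reactions.append(Reaction("BAD", {"glc_c": -1, "pyr_c": 1}, 0, 10))
    broken.validate()
    qc = qc_model(broken)
    n_internal = len(broken.reactions) - len(broken.exchange_ids) - 1
    assert qc.mass_balanced_fraction == pytest.approx((n_internal - 1) / n_internal)
    # glc -> pyr is mass-unbalanced yet still admits positive metabolite
    # masses, so the consistency metric rightly stays at 1
    assert qc.stoichiometric_consistency == 1.0


def test_qc_detects_stoichiometric_inconsistency(toy_network):
    broken = toy_network.copy()
    # a duplication reaction forces the metabolite's conserved mass to 0
    broken.reactions.append(Reaction("DUP", {"glc_c": 1}, 0, 10))
    broken.validate()
    qc = qc_model(broken)
    assert qc.stoichiometric_consistency < 1.0


def test_qc_disconnected_metabolite(toy_network, medium):
    branch = fatty_acid_branch_reactions(toy_network)
    ctx = ContextModel(toy_network,
                       set(toy_network.reaction_ids) - branch, set(), medium)
    qc = qc_model(ctx)
    assert qc.metabolite_connectivity_fraction < 1.0


# -- model stats -----------------------------------------------------------

def test_model_stats_identical_models(toy_network, medium):
    kept = set(toy_network.reaction_ids)
    models = [ContextModel(toy_network, kept, set(), medium, f"s{i}", g)
              for i, g in enumerate(["WT_VEH", "WT_VEH", "AD_VEH", "AD_VEH",
                                     "AD_NFP", "AD_NFP"])]
    stats = model_stats(models)
    venn = stats["reaction_venn"]
    assert venn["111"] == len(kept)
    assert sum(venn.values()) == len(kept)


def test_model_stats_counts_match_independent_tally(study):
    stats = study.content_stats
    for group in ("WT_VEH", "AD_VEH", "AD_NFP"):
        members = [m for m in study.models.values() if m.group == group]
        assert stats["mean_counts"][group]["reactions"] == pytest.approx(
            np.mean([len(m.kept_reactions | m.gapfilled_reactions) for m in members]))
        mets = [len({mid for rid in m.reaction_ids
                     for mid in m.parent.reaction(rid).stoichiometry})
                for m in members]
        assert stats["mean_counts"][group]["metabolites"] == pytest.approx(np.mean(mets))


def test_restoration_of_model_size(study):
    """Treated-group model size sits closer to control than the disease
    group does (network-content restoration)."""
    counts = {g: study.content_stats["mean_counts"][g]["reactions"]
              for g in ("WT_VEH", "AD_VEH", "AD_NFP")}
    assert (abs(counts["AD_NFP"] - counts["WT_VEH"])
            < abs(counts["AD_VEH"] - counts["WT_VEH"]))
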