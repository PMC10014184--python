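"""End-to-end study pipeline on the synthetic three-group design.

Chains the stages: simulate (or load) a proteome and network, run the
differential-proteome statistics, extract one gap-filled context model
per sample, fit LAD fluxes, profile flux-sums and classify restoration
across the control/disease/treated groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .flux_analysis import FluxState, expression_targets, flux_sum, lad_fit
from .group_comparison import compare_all
from .model_extraction import (ContextModel, extract_context, gapfill_growth,
                               model_stats, score_reactions)
from .network import MetabolicNetwork
from .proteome_stats import anova_bh, cluster_deps, tukey_select, zscore_normalize
from .synthetic_data import (EffectSizes, ProteomeMatrix, SyntheticTruth,
                             ToyNetworkConfig, default_medium,
                             generate_toy_network, simulate_proteome)

__all__ = ["StudyResult", "run_pipeline", "run_models"]


@dataclass
class StudyResult:
    network: MetabolicNetwork
    proteome: ProteomeMatrix
    truth: SyntheticTruth | None
    dep_table: pd.DataFrame
    clusters: pd.Series | None
    regulated: "object"
    models: dict[str, ContextModel]
    flux_states: dict[str, FluxState]
    flux_sums: dict[str, pd.Series]
    comparison: pd.DataFrame
    content_stats: dict = field(default_factory=dict)

    def labels(self, kind: str = "flux_sum") -> pd.Series:
        sub = self.comparison[self.comparison.entity_kind == kind]
        return pd.Series(sub.label.values, index=sub.entity_id.values)


def run_models(network: MetabolicNetwork, proteome: ProteomeMatrix,
               medium: dict[str, float], v_min: float = 1e-3,
               mode: str = "exact") -> tuple[dict, dict, dict]:
    """Per-sample context models, LAD flux states and flux-sum profiles."""
    from .model_extraction import flux_capacities

    models: dict[str, ContextModel] = {}
    flux_states: dict[str, FluxState] = {}
    flux_sums: dict[str, pd.Series] = {}
    caps = flux_capacities(network.apply_medium(medium))  # shared across samples
    for sample in proteome.samples:
        expr = proteome.sample_expression(sample)
        scores = score_reactions(network, expr)
        ctx = extract_context(network, scores, medium, v_min=v_min, mode=mode,
                              sample_id=sample, group=str(proteome.design[sample]),
                              flux_caps=caps)
        ctx = gapfill_growth(ctx, v_min=v_min, flux_caps=caps)
        targets = expression_targets(ctx, expr)
        state = lad_fit(ctx, targets, v_min=v_min)
        models[sample] = ctx
        flux_states[sample] = state
        flux_sums[sample] = flux_sum(ctx, state)
    return models, flux_states, flux_sums


def run_pipeline(seed: int = 0,
                 config: ToyNetworkConfig = ToyNetworkConfig(),
                 effects: EffectSizes = EffectSizes(),
                 design: tuple[int, int, int] = (3, 9, 6),
                 alpha: float = 0.05, k: int = 4,
                 v_min: float = 1e-3, mode: str = "exact") -> StudyResult:
    """Simulate one study and run every analysis stage on it."""
    network = generate_toy_network(config)
    medium = default_medium(config)
    proteome, truth = simulate_proteome(network, design, effects, seed)

    dep = anova_bh(proteome, alpha=alpha)
    z, _ = zscore_normalize(proteome)
    sig = z.loc[dep.index[dep.significant]]
    clusters = None
    if len(sig) >= k:
        clusters, _ = cluster_deps(sig, proteome.design, k=k)
    regulated = tukey_select(proteome, alpha=alpha, prefilter=dep)

    models, flux_states, flux_sums = run_models(network, proteome, medium,
                                                v_min=v_min, mode=mode)
    comparison = compare_all(flux_states, flux_sums, proteome.design, alpha=alpha)
    return StudyResult(network, proteome, truth, dep, clusters, regulated,
                       models, flux_states, flux_sums, comparison,
                       model_stats(list(models.values())))
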