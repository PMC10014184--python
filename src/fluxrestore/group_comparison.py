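"""Three-group comparison of fluxes and flux-sums with restoration labels.

Each reaction (flux) and each compartment-qualified metabolite
(flux-sum) is compared across the control, disease and treated groups
with two-sided Wilcoxon rank-sum (Mann-Whitney) tests.  The restoration
classification follows the disease/treatment contrast: an entity whose
value rises in disease relative to control and falls back under
treatment is a "decreased" entity (the treatment decreased it again),
promoted to "significantly decreased" when both rank-sum tests reject at
the chosen level; the mirrored rule yields the "increased" labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wilcoxon_rank_sum",
    "classify_restoration",
    "compare_all",
    "embed_samples",
    "LABELS",
]

LABELS = (
    "unchanged",
    "decreased_flux_sum",
    "significantly_decreased_flux_sum",
    "increased_flux_sum",
    "significantly_increased_flux_sum",
)

_EXACT_MAX_N = 10  # exact enumeration when min(n1, n2) <= this and no ties


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the Mann-Whitney U statistic.

    ``counts[u]`` is the number of arrangements of n1 + n2 distinct
    values giving U = u for the first sample; classic lattice-path
    recurrence, total mass C(n1 + n2, n1).
    """
    # f(a, b)[u]: arrangements of a first-sample and b second-sample items
    # with U = u; the largest item comes from sample 1 (adding b won pairs)
    # or from sample 2 (adding none):
    #   f(a, b)[u] = f(a-1, b)[u-b] + f(a, b-1)[u]
    size = n1 * n2 + 1
    prev = np.zeros((n2 + 1, size))  # a = 0
    prev[:, 0] = 1.0
    for a in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0  # b = 0
        for b in range(1, n2 + 1):
            cur[b] = cur[b - 1]
            cur[b, b:] += prev[b, :size - b]
        prev = cur
    return prev[n2]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns ``(U, p)`` where U is the statistic of *x*.  The p-value is
    exact (full enumeration of the null) for small samples without ties,
    otherwise a normal approximation with midrank tie correction and
    continuity correction.  Identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need >= 2 values")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    U = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(combined)) < n1 + n2

    if not has_ties and min(n1, n2) <= _EXACT_MAX_N:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_int = int(round(U))
        p_low = counts[:u_int + 1].sum() / total
        p_high = counts[u_int:].sum() / total
        return U, min(1.0, 2.0 * min(p_low, p_high))

    mu = n1 * n2 / 2.0
    N = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1)))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return U, 1.0
    z = max(0.0, abs(U - mu) - 0.5) / math.sqrt(var)
    return U, float(2.0 * stats.norm.sf(z))


@dataclass
class RestorationResult:
    label: str
    p_disease_vs_control: float
    p_treated_vs_disease: float
    medians: dict[str, float]


def classify_restoration(control, disease, treated,
                         alpha: float = 0.05) -> RestorationResult:
    """Label one entity's replicate values by the restoration pattern.

    decreased:  median(disease) > median(control) and
                median(treated) < median(disease)
                (elevated by disease, lowered again by treatment);
    increased:  the mirrored pattern;
    each promoted to significantly_* when both Wilcoxon rank-sum tests
    (disease vs control, treated vs disease) reject at *alpha*.
    """
    control = np.asarray(control, dtype=float)
    disease = np.asarray(disease, dtype=float)
    treated = np.asarray(treated, dtype=float)
    m_c, m_d, m_t = (float(np.median(v)) for v in (control, disease, treated))
    _, p_dc = wilcoxon_rank_sum(disease, control)
    _, p_td = wilcoxon_rank_sum(treated, disease)
    if m_d > m_c and m_t < m_d:
        label = "decreased_flux_sum"
        if p_dc < alpha and p_td < alpha:
            label = "significantly_decreased_flux_sum"
    elif m_d < m_c and m_t > m_d:
        label = "increased_flux_sum"
        if p_dc < alpha and p_td < alpha:
            label = "significantly_increased_flux_sum"
    else:
        label = "unchanged"
    return RestorationResult(label, p_dc, p_td,
                             {"control": m_c, "disease": m_d, "treated": m_t})


def compare_all(flux_states: dict[str, "pd.Series | object"],
                flux_sums: dict[str, pd.Series],
                design: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Per-entity three-group comparison table.

    *flux_states* maps sample id -> per-reaction flux Series (or a
    FluxState, whose ``.fluxes`` is used); *flux_sums* maps sample id ->
    per-metabolite flux-sum Series.  Entities absent from a sample's
    model contribute 0 (flagged in the ``imputed`` column: absence means
    no capacity).  Rows are sorted by the absolute disease-vs-treated
    median difference, largest change first.
    """
    samples = list(design.index)
    missing = [s for s in samples if s not in flux_states or s not in flux_sums]
    if missing:
        raise ValueError(f"samples without flux data: {missing}")

    def as_series(obj) -> pd.Series:
        return obj.fluxes if hasattr(obj, "fluxes") else obj

    records = []
    for kind, per_sample in (("flux", {s: as_series(flux_states[s]) for s in samples}),
                             ("flux_sum", flux_sums)):
        entities = sorted(set().union(*[v.index for v in per_sample.values()]))
        table = pd.DataFrame(
            {s: per_sample[s].reindex(entities) for s in samples}, index=entities)
        imputed = table.isna().any(axis=1)
        table = table.fillna(0.0)
        for ent in entities:
            by_group = {g: table.loc[ent, design.index[design == g]].to_numpy()
                        for g in ("WT_VEH", "AD_VEH", "AD_NFP")}
            res = classify_restoration(by_group["WT_VEH"], by_group["AD_VEH"],
                                       by_group["AD_NFP"], alpha)
            records.append({
                "entity_id": ent, "entity_kind": kind,
                "median_WT_VEH": res.medians["control"],
                "median_AD_VEH": res.medians["disease"],
                "median_AD_NFP": res.medians["treated"],
                "p_AD_vs_WT": res.p_disease_vs_control,
                "p_NFP_vs_AD": res.p_treated_vs_disease,
                "label": res.label,
                "imputed": bool(imputed[ent]),
            })
    df = pd.DataFrame.from_records(records)
    df["abs_change"] = (df["median_AD_VEH"] - df["median_AD_NFP"]).abs()
    df = df.sort_values("abs_change", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def embed_samples(features: pd.DataFrame, n_neighbors: int = 5,
                  seed: int = 0, min_dist: float = 0.1) -> pd.DataFrame:
    """2-D UMAP embedding of sample feature vectors.

    *features* is samples x features — protein abundances for the
    proteome view (default ``n_neighbors=5``) or binary reaction-presence
    vectors of the context models (use ``n_neighbors=11``).  Deterministic
    for a fixed seed.
    """
    if n_neighbors >= len(features):
        raise ValueError("n_neighbors must be smaller than the sample count")
    import warnings

    import umap  # deferred: slow import

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism
        warnings.simplefilter("ignore", UserWarning)
        coords = reducer.fit_transform(features.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=features.index, columns=["umap1", "umap2"])
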