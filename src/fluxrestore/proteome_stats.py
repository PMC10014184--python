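"""Three-group differential proteome statistics.

Implements the statistical chain applied to the protein abundance
matrix: per-protein Z-score normalization, one-way ANOVA across the
three groups with Benjamini-Hochberg FDR control, agglomerative
hierarchical clustering of the differentially expressed proteins (DEPs)
into four clusters labelled by their disease/treatment response pattern,
Tukey HSD (Tukey-Kramer for unequal n) post-hoc selection of
treatment-regulated proteins, and presence Venn counts across groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .synthetic_data import GROUPS, ProteomeMatrix

__all__ = [
    "zscore_normalize",
    "anova_bh",
    "cluster_deps",
    "tukey_select",
    "presence_venn",
    "RegulatedSet",
]


@dataclass
class RegulatedSet:
    """Proteins significantly regulated by treatment (AD_NFP vs AD_VEH)."""

    upregulated: set[str]
    downregulated: set[str]

    def __post_init__(self) -> None:
        if self.upregulated & self.downregulated:
            raise ValueError("a protein cannot be both up- and downregulated")


def zscore_normalize(matrix: ProteomeMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise Z-score (population SD, divide by n).

    Returns the normalized matrix and the list of constant rows, which
    are mapped to all-zero and flagged rather than dropped.
    """
    df = matrix.abundances if isinstance(matrix, ProteomeMatrix) else matrix
    if df.size == 0:
        raise ValueError("empty matrix")
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    return (pd.DataFrame(z, index=df.index, columns=df.columns),
            list(df.index[constant]))


def anova_bh(matrix: ProteomeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein one-way fixed-effects ANOVA with BH step-up q-values.

    Returns a DataFrame indexed by protein with columns ``F``, ``p``,
    ``q`` and ``significant`` (q < alpha).
    """
    groups = sorted(matrix.design.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    cols = {g: matrix.group_samples(g) for g in groups}
    if any(len(c) < 2 for c in cols.values()):
        raise ValueError("every group needs >= 2 samples")
    blocks = [matrix.abundances[c].to_numpy(dtype=float) for c in cols.values()]
    F, p = stats.f_oneway(*blocks, axis=1)
    # degenerate rows (all values identical) give nan; treat as no signal
    F = np.nan_to_num(F, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"F": F, "p": p, "q": q, "significant": q < alpha},
        index=matrix.abundances.index)


def _relabel_clusters(z: pd.DataFrame, raw_labels: np.ndarray,
                      design: pd.Series) -> dict[int, int]:
    """Map raw dendrogram-cut labels to the 1-4 response semantics.

    Cluster 1 = up in disease vs control, 4 = down in disease; 2/3 =
    disease-insensitive (2 = treatment-raised, 3 = treatment-lowered).
    Assignment is by centroid group-mean contrasts, ranked so each
    semantic label is used once.
    """
    from scipy.optimize import linear_sum_assignment

    wt = design.index[design == "WT_VEH"]
    ad = design.index[design == "AD_VEH"]
    nfp = design.index[design == "AD_NFP"]
    labs = list(np.unique(raw_labels))
    contrasts = np.zeros((len(labs), 2))
    for i, lab in enumerate(labs):
        centroid = z[raw_labels == lab]
        contrasts[i, 0] = centroid[ad].values.mean() - centroid[wt].values.mean()
        contrasts[i, 1] = centroid[nfp].values.mean() - centroid[wt].values.mean()
    norms = np.linalg.norm(contrasts, axis=1, keepdims=True)
    contrasts = contrasts / np.where(norms > 0, norms, 1.0)
    # response archetypes in (AD-WT, NFP-WT) contrast space:
    # 1 = disease-up restored, 4 = disease-down restored,
    # 2 = treatment-raised only, 3 = treatment-lowered only
    archetypes = {1: (1.0, 0.0), 4: (-1.0, 0.0), 2: (0.0, 1.0), 3: (0.0, -1.0)}
    sems = list(archetypes)
    sizes = np.array([(raw_labels == lab).sum() for lab in labs], dtype=float)
    # weight by cluster size: maximize summed per-protein agreement so a
    # stray singleton cannot claim a semantic label from a large cluster
    cost = -(sizes[:, None] * (contrasts @ np.array([archetypes[s] for s in sems]).T))
    rows, cols = linear_sum_assignment(cost)
    return {labs[r]: sems[c] for r, c in zip(rows, cols)}


def cluster_deps(normalized: pd.DataFrame, design: pd.Series,
                 k: int = 4) -> tuple[pd.Series, pd.DataFrame]:
    """Agglomerative clustering of Z-scored DEP rows into *k* clusters.

    Euclidean distance with average linkage; the tree is cut at *k* and,
    for k = 4, clusters are relabelled by their response semantics.
    Returns the per-protein cluster labels and the matrix reordered by
    dendrogram leaf order (heatmap order).
    """
    if len(normalized) < k:
        raise ValueError(f"need >= {k} significant proteins to form {k} clusters")
    # sort columns by design for a stable result under sample permutation
    col_order = list(design.sort_values(kind="stable").index)
    z = normalized[col_order]
    link = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(raw)) == k and k == 4:
        mapping = _relabel_clusters(z, raw, design)
        labels = np.array([mapping[l] for l in raw])
    else:
        labels = raw
    order = hierarchy.leaves_list(link)
    return (pd.Series(labels, index=normalized.index, name="cluster"),
            normalized.iloc[order])


def tukey_select(matrix: ProteomeMatrix, alpha: float = 0.05,
                 prefilter: pd.DataFrame | None = None) -> RegulatedSet:
    """Tukey HSD post-hoc selection of treatment-regulated proteins.

    For every protein (optionally restricted to ANOVA-significant rows
    via *prefilter*, the output of :func:`anova_bh`), the AD_VEH vs
    AD_NFP contrast is tested with the Tukey-Kramer studentized-range
    procedure; significant proteins are partitioned by the sign of the
    treatment effect.
    """
    groups = sorted(matrix.design.unique())
    if set(groups) != set(GROUPS):
        raise ValueError(f"expected the three groups {GROUPS}, got {groups}")
    proteins = matrix.proteins
    if prefilter is not None:
        proteins = [p for p in proteins if bool(prefilter.loc[p, "significant"])]
    cols = {g: matrix.group_samples(g) for g in GROUPS}
    up, down = set(), set()
    for p in proteins:
        samples = [matrix.abundances.loc[p, cols[g]].to_numpy(dtype=float)
                   for g in GROUPS]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            continue
        res = stats.tukey_hsd(*samples)
        i_ad, i_nfp = GROUPS.index("AD_VEH"), GROUPS.index("AD_NFP")
        if res.pvalue[i_ad, i_nfp] < alpha:  # strict: ties at alpha excluded
            diff = samples[i_nfp].mean() - samples[i_ad].mean()
            if diff > 0:
                up.add(p)
            elif diff < 0:
                down.add(p)
    return RegulatedSet(up, down)


def presence_venn(sets: dict[str, set]) -> dict[str, int]:
    """Counts of the 7 intersection regions of three presence sets.

    Keys are '100', '010', ..., '111' in the order of the sorted set
    names (1 = member of that set).  Region counts sum to |union|.
    """
    if len(sets) != 3:
        raise ValueError("exactly three sets required")
    names = sorted(sets)
    union = set().union(*sets.values())
    counts = {k: 0 for k in ("100", "010", "001", "110", "101", "011", "111")}
    for el in union:
        key = "".join("1" if el in sets[n] else "0" for n in names)
        counts[key] += 1
    return counts
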