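"""Differential-proteome statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluxrestore.proteome_stats import (anova_bh, cluster_deps, presence_venn,
                                        tukey_select, zscore_normalize)
from fluxrestore.synthetic_data import ProteomeMatrix, simulate_proteome


def _matrix(values: np.ndarray, design: list[str]) -> ProteomeMatrix:
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ProteomeMatrix(
        pd.DataFrame(values, index=[f"p{i}" for i in range(values.shape[0])],
                     columns=samples),
        pd.Series(design, index=samples, name="group"))


# -- Z-score ---------------------------------------------------------------

def test_zscore_closed_form():
    z, flags = zscore_normalize(pd.DataFrame([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(z.values[0], [-1.22474487, 0.0, 1.22474487],
                               atol=1e-8)
    assert flags == []


def test_zscore_constant_row_flagged():
    z, flags = zscore_normalize(pd.DataFrame([[5.0, 5.0, 5.0]], index=["c"]))
    np.testing.assert_array_equal(z.values[0], [0.0, 0.0, 0.0])
    assert flags == ["c"]
    with pytest.raises(ValueError):
        zscore_normalize(pd.DataFrame())


def test_zscore_rows_standardized(proteome_truth):
    proteome, _ = proteome_truth
    z, _ = zscore_normalize(proteome)
    assert np.abs(z.values.mean(axis=1)).max() < 1e-12
    np.testing.assert_allclose(z.values.std(axis=1), 1.0, atol=1e-12)


# -- ANOVA + BH ------------------------------------------------------------

def _anova_oracle(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brute-force sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, float(stats.f.sf(F, df_b, df_w))


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Hand BH step-up: q_(i) = min over j>=i of m*p_(j)/j."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


def test_anova_matches_ss_oracle():
    rng = np.random.default_rng(0)
    values = rng.lognormal(3, 0.4, size=(20, 18))
    design = ["WT_VEH"] * 3 + ["AD_VEH"] * 9 + ["AD_NFP"] * 6
    pm = _matrix(values, design)
    res = anova_bh(pm)
    for i, p in enumerate(pm.proteins):
        groups = [values[i, :3], values[i, 3:12], values[i, 12:]]
        F, pval = _anova_oracle(groups)
        assert res.loc[p, "F"] == pytest.approx(F, abs=1e-10)
        assert res.loc[p, "p"] == pytest.approx(pval, abs=1e-10)
    np.testing.assert_allclose(res["q"], _bh_oracle(res["p"].to_numpy()),
                               atol=1e-12)


def test_bh_hand_example():
    q = _bh_oracle(np.array([0.01, 0.02, 0.03, 0.5]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
    # the implementation's BH (statsmodels) agrees
    from statsmodels.stats.multitest import multipletests
    _, q2, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
    np.testing.assert_allclose(q2, [0.04, 0.04, 0.04, 0.5])


def test_bh_monotone_in_p_rank(proteome_truth):
    proteome, _ = proteome_truth
    res = anova_bh(proteome).sort_values("p")
    assert (np.diff(res["q"].to_numpy()) >= -1e-15).all()
    assert res["q"].between(0, 1).all()


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(1)
    values = rng.normal(10, 1, size=(5, 8))
    pm = _matrix(values, ["A"] * 4 + ["B"] * 4)
    res = anova_bh(pm)
    for i, p in enumerate(pm.proteins):
        t, pt = stats.ttest_ind(values[i, :4], values[i, 4:])
        assert res.loc[p, "F"] == pytest.approx(t ** 2, rel=1e-10)
        assert res.loc[p, "p"] == pytest.approx(pt, rel=1e-10)


def test_near_constant_rows_never_significant():
    values = np.full((3, 9), 7.0) + np.random.default_rng(2).normal(0, 1e-9, (3, 9))
    pm = _matrix(values, ["A", "A", "A", "B", "B", "B", "C", "C", "C"])
    res = anova_bh(pm)
    assert not res["significant"].any()
    assert (res["p"] > 0.05).all()


def test_singleton_group_rejected():
    values = np.ones((2, 4)) + np.arange(4)
    with pytest.raises(ValueError, match=">= 2 samples"):
        _matrix(values, ["A", "A", "A", "B"])


def test_type_i_error_control_under_null(toy_network):
    """On effect-free data the fraction of q < 0.05 calls stays near zero
    (BH controls FDR, so discoveries on a global null are rare)."""
    rate = []
    rng = np.random.default_rng(3)
    for _ in range(100):
        values = rng.lognormal(3, 0.3, size=(50, 18))
        pm = _matrix(values, ["WT_VEH"] * 3 + ["AD_VEH"] * 9 + ["AD_NFP"] * 6)
        res = anova_bh(pm)
        rate.append(res["significant"].mean())
    mean_rate = float(np.mean(rate))
    se = float(np.std(rate) / np.sqrt(len(rate)))
    assert mean_rate <= 0.05 + 2 * se


# -- clustering ------------------------------------------------------------

def test_cluster_separable_archetypes():
    rng = np.random.default_rng(4)
    up = np.tile([0, 0, 0, 3, 3, 3, 3, 3, 3, 0, 0, 0, 0, 0, 0], (10, 1))
    down = -up
    values = np.vstack([up, down]) + rng.normal(0, 0.1, (20, 15))
    design = pd.Series(["WT_VEH"] * 3 + ["AD_VEH"] * 6 + ["AD_NFP"] * 6,
                       index=[f"s{i}" for i in range(15)])
    df = pd.DataFrame(values, index=[f"p{i}" for i in range(20)],
                      columns=design.index)
    labels, _ = cluster_deps(df, design, k=2)
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels.iloc[0] != labels.iloc[10]


def test_cluster_sample_order_invariance(proteome_truth):
    proteome, _ = proteome_truth
    from fluxrestore.proteome_stats import anova_bh as _anova
    dep = _anova(proteome)
    z, _ = zscore_normalize(proteome)
    sig = z.loc[dep.index[dep.significant]]
    labels, _ = cluster_deps(sig, proteome.design)
    perm = list(reversed(sig.columns))
    labels2, _ = cluster_deps(sig[perm], proteome.design.loc[perm])
    assert labels.equals(labels2)


def test_cluster_requires_enough_proteins(proteome_truth):
    proteome, _ = proteome_truth
    z, _ = zscore_normalize(proteome)
    with pytest.raises(ValueError, match="significant proteins"):
        cluster_deps(z.iloc[:3], proteome.design, k=4)


def test_cluster1_recall_of_planted_branch(toy_network):
    """Disease-elevated, treatment-restored proteins land in cluster 1."""
    hits = total = 0
    for seed in range(20):
        proteome, truth = simulate_proteome(toy_network, seed=seed)
        dep = anova_bh(proteome)
        z, _ = zscore_normalize(proteome)
        labels, _ = cluster_deps(z.loc[dep.index[dep.significant]], proteome.design)
        c1 = [p for p, c in truth.cluster_of_protein.items() if c == 1]
        hits += sum(1 for p in c1 if p in labels.index and labels[p] == 1)
        total += len(c1)
    assert hits / total >= 0.9


# -- Tukey post hoc --------------------------------------------------------

def _tukey_oracle_p(groups: list[np.ndarray], i: int, j: int) -> float:
    """Studentized-range recomputation of the Tukey-Kramer p-value."""
    k = len(groups)
    N = sum(len(g) for g in groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (N - k)
    se = np.sqrt(mse / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
    q = abs(groups[i].mean() - groups[j].mean()) / se
    return float(stats.studentized_range.sf(q, k, N - k))


def test_tukey_matches_studentized_range_oracle():
    rng = np.random.default_rng(5)
    groups = [rng.normal(10, 1, 3), rng.normal(12, 1, 9), rng.normal(11, 1, 6)]
    res = stats.tukey_hsd(*groups)
    for i in range(3):
        for j in range(i + 1, 3):
            assert res.pvalue[i, j] == pytest.approx(
                _tukey_oracle_p(groups, i, j), abs=1e-6)


def test_tukey_select_directions(toy_network):
    proteome, truth = simulate_proteome(toy_network, seed=1)
    dep = anova_bh(proteome)
    reg = tukey_select(proteome, prefilter=dep)
    assert not (reg.upregulated & reg.downregulated)
    # branch proteins are AD-up and NFP-restored, i.e. down under treatment
    c1 = {p for p, c in truth.cluster_of_protein.items() if c == 1}
    assert len(reg.downregulated & c1) >= 0.8 * len(c1)
    # treatment-raised planted proteins appear as upregulated
    c2 = {p for p, c in truth.cluster_of_protein.items() if c == 2}
    assert len(reg.upregulated & c2) >= 0.5 * len(c2)


def test_tukey_equal_means_excluded():
    values = np.vstack([np.concatenate([np.random.default_rng(6).lognormal(0, 1, 3),
                                        [5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])])
    pm = _matrix(values, ["WT_VEH"] * 3 + ["AD_VEH"] * 3 + ["AD_NFP"] * 3)
    reg = tukey_select(pm)
    assert reg.upregulated == set() and reg.downregulated == set()


def test_tukey_requires_three_groups():
    values = np.random.default_rng(7).lognormal(size=(2, 6))
    pm = _matrix(values, ["A"] * 3 + ["B"] * 3)
    with pytest.raises(ValueError, match="three groups"):
        tukey_select(pm)


# -- Venn ------------------------------------------------------------------

def test_venn_hand_examples():
    counts = presence_venn({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
    assert counts["111"] == 1 and sum(counts.values()) == 3
    same = presence_venn({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
    assert same["111"] == 2 and sum(same.values()) == 2


def test_venn_matches_inclusion_exclusion():
    rng = np.random.default_rng(8)
    sets = {n: set(rng.integers(0, 40, 25).tolist()) for n in "ABC"}
    counts = presence_venn(sets)
    assert sum(counts.values()) == len(sets["A"] | sets["B"] | sets["C"])
    # brute-force membership tabulation
    for el in sets["A"] | sets["B"] | sets["C"]:
        key = "".join("1" if el in sets[n] else "0" for n in sorted(sets))
        counts[key] -= 1
    assert all(v == 0 for v in counts.values())
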