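"""PCA, Ward clustering, tree cuts, v-tests and growth-form assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.stats import norm

from grazeform.growthform import (
    ClusterTree,
    assign_growth_forms,
    cut_tree,
    name_clusters,
    pca,
    range_standardize,
    vtest,
    ward_cluster,
)
from grazeform.simulate import simulate_species_pool, SimulationConfig
from grazeform.traits import build_trait_table


# ---------------------------------------------------------------------------
# range standardization
# ---------------------------------------------------------------------------

def test_range_standardize_maps_to_unit_interval():
    df = pd.DataFrame({"a": [1.0, 3.0, 5.0], "b": [0.0, 0.5, 1.0]})
    out, ranges = range_standardize(df)
    assert list(out["a"]) == [0.0, 0.5, 1.0]
    assert list(out["b"]) == [0.0, 0.5, 1.0]  # already spanning [0,1]: unchanged
    assert ranges.loc["min", "a"] == 1.0 and ranges.loc["max", "a"] == 5.0


def test_range_standardize_constant_column_errors():
    with pytest.raises(ValueError, match="b"):
        range_standardize(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 2.0]}))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _random_table(rng, n=20, p=4):
    return pd.DataFrame(rng.standard_normal((n, p)), columns=[f"v{i}" for i in range(p)])


def test_pca_variance_conservation_and_reconstruction():
    rng = np.random.default_rng(0)
    for unit_variance in (True, False):
        table = _random_table(rng)
        res = pca(table, unit_variance=unit_variance)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)
        X = ((table - res.center) / res.scale).to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - X).max() < 1e-8


def test_pca_components_orthogonal():
    res = pca(_random_table(np.random.default_rng(1)))
    V = res.loadings.to_numpy()
    assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)


def test_pca_two_correlated_variables_put_all_variance_on_pc1():
    x = np.linspace(0, 1, 10)
    res = pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
    assert res.variance_pct[0] == pytest.approx(100.0, abs=1e-9)


def test_pca_sign_convention_deterministic():
    table = _random_table(np.random.default_rng(2))
    res = pca(table)
    for c in res.loadings.columns:
        col = res.loadings[c]
        assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0
    res2 = pca(table.iloc[::-1])  # row order must not matter
    pd.testing.assert_frame_equal(res.loadings, res2.loadings, atol=1e-10, rtol=0)


def test_pca_matches_eigendecomposition_of_correlation_matrix():
    table = _random_table(np.random.default_rng(3), n=30)
    res = pca(table, unit_variance=True)
    Z = (table - table.mean()) / table.std(ddof=0)
    ev = np.sort(np.linalg.eigvalsh(np.corrcoef(Z.to_numpy().T)))[::-1]
    assert np.allclose(res.variance_pct, 100 * ev / ev.sum(), atol=1e-8)


def test_pca_rejects_degenerate_input():
    with pytest.raises(ValueError):
        pca(pd.DataFrame({"a": [1.0]}))
    with pytest.raises(ValueError):
        pca(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def _brute_force_ward(X):
    """Greedy Ward merges found by exhaustively scoring every cluster pair
    with the within-cluster sum-of-squares increase."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = X[clusters[a]].mean(0), X[clusters[b]].mean(0)
            na, nb = len(clusters[a]), len(clusters[b])
            d_sse = na * nb / (na + nb) * np.sum((ma - mb) ** 2)
            if best is None or d_sse < best[0] - 1e-12:
                best = (d_sse, (a, b))
        d_sse, (a, b) = best
        merges.append((a, b, np.sqrt(2 * d_sse)))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_two_identical_points_merge_at_zero():
    tree = ward_cluster(np.array([[1.0, 2.0], [1.0, 2.0]]))
    assert tree.merges == [(0, 1, 0.0)]


def test_two_separated_triplets_join_last():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 0.1, (3, 2)), rng.normal(10, 0.1, (3, 2))])
    tree = ward_cluster(X)
    labels = cut_tree(tree, 2)
    assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
    assert labels[0] != labels[3]
    # final merge agrees with exhaustive Ward
    oracle = _brute_force_ward(X)
    assert tree.merges[-1][2] == pytest.approx(oracle[-1][2], rel=1e-9)


@pytest.mark.parametrize("seed", range(50))
def test_ward_matches_exhaustive_search_small_n(seed):
    """Merge sequence and heights agree with exhaustively scored Ward for n <= 7."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    X = rng.standard_normal((n, int(rng.integers(1, 4))))
    tree = ward_cluster(X)
    oracle = _brute_force_ward(X)
    for (a, b, h), (oa, ob, oh) in zip(tree.merges, oracle):
        assert {a, b} == {oa, ob}
        assert h == pytest.approx(oh, rel=1e-9)


def test_ward_heights_non_decreasing_and_match_scipy():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((25, 4))
    tree = ward_cluster(X)
    heights = [h for _, _, h in tree.merges]
    assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
    Z = hierarchy.linkage(X, method="ward")
    assert np.allclose(sorted(heights), sorted(Z[:, 2]), atol=1e-8)
    # identical partitions at k = 4
    ours = cut_tree(tree, 4)
    theirs = hierarchy.fcluster(Z, 4, criterion="maxclust")
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(ours, theirs) == 1.0


def test_cut_tree_extremes_and_bounds():
    tree = ward_cluster(np.arange(5.0)[:, None])
    assert len(set(cut_tree(tree, 1))) == 1
    assert len(set(cut_tree(tree, 5))) == 5
    with pytest.raises(ValueError):
        cut_tree(tree, 0)
    with pytest.raises(ValueError):
        cut_tree(tree, 6)


def test_cut_tree_labels_ordered_by_size():
    X = np.array([0.0, 0.1, 0.2, 0.3, 10.0, 10.1, 20.0])[:, None]
    labels = cut_tree(ward_cluster(X), 3)
    sizes = np.bincount(labels)
    assert list(sizes) == sorted(sizes, reverse=True)
    assert labels[0] == 0  # biggest cluster labelled first


# ---------------------------------------------------------------------------
# v-tests
# ---------------------------------------------------------------------------

def _brute_vtest(x, mask):
    """Direct evaluation of the random-subset v statistic."""
    x = np.asarray(x, dtype=float)
    N, n_k = len(x), mask.sum()
    s2 = x.var()
    denom = np.sqrt(s2 / n_k * (N - n_k) / (N - 1))
    return (x[mask].mean() - x.mean()) / denom


def test_vtest_hand_example():
    """values {0,0,1,1}, cluster = last two -> 0.5 / sqrt((0.25/2)(2/3))."""
    df = pd.DataFrame({"t": [0.0, 0.0, 1.0, 1.0]})
    out = vtest(df, np.array([0, 0, 1, 1]))
    v = out[(out.cluster == 1) & (out.trait == "t")]["v"].iloc[0]
    assert v == pytest.approx(np.sqrt(3), abs=1e-4)  # = 1.7321
    assert out[(out.cluster == 1)]["p"].iloc[0] == pytest.approx(
        2 * norm.sf(np.sqrt(3)), rel=1e-9
    )


def test_vtest_whole_sample_cluster_is_zero():
    df = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
    out = vtest(df, np.zeros(3, dtype=int))
    assert out["v"].iloc[0] == 0.0
    assert out["degenerate"].iloc[0]


def test_vtest_constant_trait_flagged():
    df = pd.DataFrame({"t": [2.0, 2.0, 2.0, 2.0]})
    out = vtest(df, np.array([0, 0, 1, 1]))
    assert (out["v"] == 0).all()
    assert out["degenerate"].all()


@pytest.mark.parametrize("seed", range(20))
def test_vtest_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    x = rng.standard_normal(n)
    labels = rng.integers(0, 3, n)
    out = vtest(pd.DataFrame({"t": x}), labels)
    for c in np.unique(labels):
        got = out[(out.cluster == c)]["v"].iloc[0]
        want = _brute_vtest(x, labels == c)
        assert got == pytest.approx(want, abs=1e-10)


def test_vtest_antisymmetric_under_reflection():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(12)
    labels = np.array([0] * 5 + [1] * 7)
    a = vtest(pd.DataFrame({"t": x}), labels)
    b = vtest(pd.DataFrame({"t": 2 * x.mean() - x}), labels)
    assert np.allclose(a["v"].to_numpy(), -b["v"].to_numpy(), atol=1e-10)


# ---------------------------------------------------------------------------
# growth-form assignment
# ---------------------------------------------------------------------------

def _archetype_trait_table(seed=0, per=12, sd_scale=1.0):
    cfg = SimulationConfig(seed=seed, n_species=4 * per)
    labels, latent = simulate_species_pool(cfg)
    ratio = np.exp(latent["log_height_ratio"])
    table = pd.DataFrame(
        {
            "culm_orientation_index": latent["culm"],
            "lateral_index": latent["lateral"],
            "tuft_index": latent["tuft"],
            "grazer_use_index": np.minimum(ratio, 1 / ratio),
            "n_quadrats": 20,
            "clustered": True,
        },
        index=latent.index,
    )
    return table, labels


def test_archetype_recovery_ari():
    from sklearn.metrics import adjusted_rand_score

    table, truth = _archetype_trait_table(seed=5)
    model = assign_growth_forms(table, k=4)
    ari = adjusted_rand_score(truth, model.assignments.loc[truth.index, "growth_form"])
    assert ari >= 0.9


def test_names_match_archetypes():
    table, truth = _archetype_trait_table(seed=6)
    model = assign_growth_forms(table, k=4)
    joined = model.assignments.join(truth)
    # the v-test signature naming should recover the generating archetype label
    agreement = (joined["growth_form"] == joined["archetype"]).mean()
    assert agreement >= 0.9


def test_override_provenance_and_unassigned_warning():
    table, _ = _archetype_trait_table(seed=7)
    table.loc[table.index[0], "clustered"] = False
    table.loc[table.index[1], "clustered"] = False
    overrides = pd.Series({table.index[0]: "resister"})
    with pytest.warns(UserWarning, match="unassigned"):
        model = assign_growth_forms(table, k=4, overrides=overrides)
    a = model.assignments
    assert a.loc[table.index[0], "growth_form"] == "resister"
    assert a.loc[table.index[0], "provenance"] == "manual_override"
    assert a.loc[table.index[1], "growth_form"] == "unassigned"


def test_assignment_deterministic(tmp_path):
    table, _ = _archetype_trait_table(seed=8)
    m1 = assign_growth_forms(table, k=4)
    m2 = assign_growth_forms(table, k=4)
    pd.testing.assert_frame_equal(m1.assignments, m2.assignments)
    m1.to_files(tmp_path / "a")
    m2.to_files(tmp_path / "b")
    assert (tmp_path / "a" / "assignments.csv").read_bytes() == (
        tmp_path / "b" / "assignments.csv"
    ).read_bytes()


def test_too_few_clustered_species_errors():
    table, _ = _archetype_trait_table()
    table["clustered"] = False
    table.iloc[:3, table.columns.get_loc("clustered")] = True
    with pytest.raises(ValueError, match="k = 4"):
        assign_growth_forms(table, k=4)


def test_recovery_rate_over_replicates():
    """Planted 4-archetype pools are recovered (ARI >= 0.9) in >= 95% of seeds."""
    from sklearn.metrics import adjusted_rand_score

    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        table, truth = _archetype_trait_table(seed=1000 + seed)
        model = assign_growth_forms(table, k=4)
        ari = adjusted_rand_score(truth, model.assignments.loc[truth.index, "growth_form"])
        hits += ari >= 0.9
    assert hits / n_rep >= 0.95
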