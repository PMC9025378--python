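import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata, spearmanr

from phyllocore.diversity import (
    DistanceMatrix,
    bray_curtis_matrix,
    hellinger_transform,
    jensen_shannon_matrix,
    pcoa,
    permdisp,
    relative_abundance,
    spearman_screen,
)
from conftest import make_table


def counts_frame(columns: dict[str, list[int]]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"t{i}" for i in range(n)], dtype=np.int64)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def test_relative_abundance_normalizes_and_rejects_empty_sample():
    rel = relative_abundance(counts_frame({"s1": [1, 4, 4]}))
    assert np.allclose(rel["s1"], [1 / 9, 4 / 9, 4 / 9])
    with pytest.raises(ValueError, match="s2"):
        relative_abundance(counts_frame({"s1": [1, 0, 0], "s2": [0, 0, 0]}))


def test_hellinger_closed_form():
    h = hellinger_transform(counts_frame({"s1": [1, 4, 4], "s2": [0, 0, 9]}))
    assert np.allclose(h["s1"], [1 / 3, 2 / 3, 2 / 3])
    assert np.allclose(h["s2"], [0, 0, 1])


@settings(max_examples=40, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(0, 1000), min_size=3, max_size=3),
        min_size=2,
        max_size=6,
    ).filter(lambda cols: all(sum(c) > 0 for c in cols))
)
def test_hellinger_columns_have_unit_norm(cols):
    frame = counts_frame({f"s{i}": c for i, c in enumerate(cols)})
    h = hellinger_transform(frame)
    assert np.allclose((h**2).sum(axis=0), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------

def test_bray_curtis_closed_forms():
    bc = bray_curtis_matrix(
        counts_frame({"a": [1, 1], "b": [1, 3], "c": [1, 1], "d": [2, 0], "e": [0, 2]})
    )
    frame = bc.to_frame()
    assert frame.at["a", "b"] == pytest.approx(1 / 3)  # |0|+|2| over 2+4
    assert frame.at["a", "c"] == 0.0
    assert frame.at["d", "e"] == 1.0  # disjoint taxa
    assert np.allclose(bc.values, bc.values.T)


def test_bray_curtis_matches_scipy_on_random_tables(rng):
    data = rng.integers(0, 50, size=(12, 8))
    data[0] += 1  # no all-zero columns
    frame = pd.DataFrame(data, index=[f"t{i}" for i in range(12)], columns=[f"s{i}" for i in range(8)])
    mine = bray_curtis_matrix(frame).values
    ref = squareform(pdist(data.T, metric="braycurtis"))
    assert np.allclose(mine, ref, atol=1e-12)


def test_jensen_shannon_bounds_and_formula_oracle():
    frame = counts_frame({"p": [1, 1], "q": [2, 0], "r": [0, 2]})
    jsd = jensen_shannon_matrix(frame, log_base=2).to_frame()
    assert jsd.at["q", "r"] == pytest.approx(1.0)  # disjoint supports
    assert jsd.at["p", "p"] == 0.0
    # brute-force entropy evaluation for P=[1/2,1/2], Q=[1,0]
    p, q = np.array([0.5, 0.5]), np.array([1.0, 0.0])
    m = (p + q) / 2

    def entropy(v):
        return -sum(x * np.log2(x) for x in v if x > 0)

    expected = entropy(m) - (entropy(p) + entropy(q)) / 2
    assert jsd.at["p", "q"] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_reconstructs_euclidean_distances(rng):
    points = rng.normal(size=(10, 4))
    d = squareform(pdist(points))
    result = pcoa(DistanceMatrix([f"s{i}" for i in range(10)], d))
    coords = result.coordinates.to_numpy()
    recon = squareform(pdist(coords))
    assert np.allclose(recon, d, atol=1e-8)
    assert np.all(np.diff(result.eigenvalues) <= 1e-9)  # decreasing axes
    assert result.proportion_explained.sum() <= 1 + 1e-12


def test_pcoa_colinear_points_use_one_axis():
    d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
    result = pcoa(DistanceMatrix(["a", "b", "c"], d))
    assert result.coordinates.shape[1] == 1
    axis = result.coordinates.iloc[:, 0].to_numpy()
    assert abs(axis[0] - axis[2]) == pytest.approx(3.0, abs=1e-9)


def test_pcoa_equilateral_symmetry():
    d = np.ones((3, 3)) - np.eye(3)
    result = pcoa(DistanceMatrix(["a", "b", "c"], d))
    pos = result.eigenvalues[result.eigenvalues > 1e-10]
    assert len(pos) == 2 and pos[0] == pytest.approx(pos[1], rel=1e-9)


def test_pcoa_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    points = rng.normal(size=(9, 3))
    d = squareform(pdist(points))
    ids = [f"s{i}" for i in range(9)]
    mine = pcoa(DistanceMatrix(ids, d))
    ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, ids))
    ref_eigs = np.sort(np.asarray(ref.eigvals))[::-1]
    k = mine.coordinates.shape[1]
    assert np.allclose(mine.eigenvalues[:k], ref_eigs[:k], atol=1e-8)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _euclid_dm(points) -> DistanceMatrix:
    return DistanceMatrix(
        [f"s{i}" for i in range(len(points))], squareform(pdist(points))
    )


def test_permdisp_mirror_groups_have_no_dispersion_difference():
    square = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
    points = np.vstack([square, square + [10, 0]])  # identical geometry, shifted
    result = permdisp(_euclid_dm(points), ["a"] * 4 + ["b"] * 4, n_perm=99, seed=3)
    assert result.F == pytest.approx(0.0, abs=1e-20)
    assert result.p_perm == 1.0


def test_permdisp_is_reproducible_and_matches_skbio_statistic(rng):
    points = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(0, 2.5, (8, 2))])
    dm = _euclid_dm(points)
    groups = ["a"] * 8 + ["b"] * 8
    first = permdisp(dm, groups, n_perm=199, seed=11)
    second = permdisp(dm, groups, n_perm=199, seed=11)
    assert first.F == second.F and first.p_perm == second.p_perm
    assert permdisp(dm, groups, n_perm=199, seed=12).seed != first.seed
    skbio = pytest.importorskip("skbio")
    ref = skbio.stats.distance.permdisp(
        skbio.DistanceMatrix(dm.values, dm.labels), groups,
        test="centroid", permutations=9,
    )
    assert first.F == pytest.approx(ref["test statistic"], rel=1e-9)


def test_permdisp_rejects_singleton_group():
    points = np.arange(10, dtype=float).reshape(5, 2)
    with pytest.raises(ValueError, match="fewer than two"):
        permdisp(_euclid_dm(points), ["a", "a", "a", "a", "b"], n_perm=9, seed=0)


def test_permdisp_p_formula():
    # p is (1 + hits) / (1 + n_perm), so it can never be exactly zero
    rng = np.random.default_rng(5)
    points = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(0, 5, (6, 2))])
    result = permdisp(_euclid_dm(points), ["a"] * 6 + ["b"] * 6, n_perm=199, seed=2)
    assert result.p_perm >= 1 / 200
    assert result.p_perm * 200 == pytest.approx(round(result.p_perm * 200))


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

def test_spearman_screen_antimonotone_pair_and_sign():
    frame = pd.DataFrame(
        {
            "s1": [1, 8, 1],
            "s2": [2, 6, 2],
            "s3": [3, 4, 4],
            "s4": [4, 2, 3],
            "s5": [5, 1, 9],
        },
        index=["up", "down", "noisy"],
        dtype=float,
    )
    result = spearman_screen(frame, top_k=3, alpha=0.05)
    pair = result.pairs.set_index(["taxon_a", "taxon_b"])
    assert pair.at[("down", "up"), "rho"] == pytest.approx(-1.0)
    assert pair.at[("down", "up"), "p_raw"] == 0.0


def test_spearman_screen_agrees_with_rank_then_pearson_oracle(rng):
    values = rng.normal(size=(7, 12))
    frame = pd.DataFrame(values, index=[f"t{i}" for i in range(7)],
                         columns=[f"s{i}" for i in range(12)])
    result = spearman_screen(frame, top_k=7, alpha=0.01)
    for _, row in result.pairs.iterrows():
        a = frame.loc[row["taxon_a"]].to_numpy()
        b = frame.loc[row["taxon_b"]].to_numpy()
        oracle_rho = pearsonr(rankdata(a), rankdata(b)).statistic
        assert row["rho"] == pytest.approx(oracle_rho, abs=1e-12)
        ref_rho, ref_p = spearmanr(a, b)
        assert row["rho"] == pytest.approx(ref_rho, abs=1e-12)
        assert row["p_raw"] == pytest.approx(ref_p, abs=1e-10)


def test_spearman_screen_excludes_constant_vectors():
    frame = pd.DataFrame(
        {"s1": [1, 5, 2], "s2": [2, 5, 1], "s3": [3, 5, 4], "s4": [4, 5, 3]},
        index=["a", "flat", "b"],
        dtype=float,
    )
    result = spearman_screen(frame, top_k=3, alpha=0.05)
    assert any("flat" in d for d in result.diagnostics)
    screened = set(result.pairs["taxon_a"]) | set(result.pairs["taxon_b"])
    assert "flat" not in screened


def test_spearman_screen_top_k_ranks_by_abundance_with_id_ties():
    frame = pd.DataFrame(
        {
            "s1": [9, 1, 9, 2],
            "s2": [9, 2, 9, 1],
            "s3": [8, 3, 8, 4],
            "s4": [8, 4, 8, 3],
        },
        index=["zeta", "low1", "acme", "low2"],
        dtype=float,
    )
    result = spearman_screen(frame, top_k=2, alpha=0.05)
    screened = set(result.pairs["taxon_a"]) | set(result.pairs["taxon_b"])
    assert screened == {"acme", "zeta"}  # equal totals: lexicographic tie-break


def test_spearman_screen_bh_adjustment_is_monotone(rng):
    values = rng.normal(size=(6, 10))
    frame = pd.DataFrame(values, index=[f"t{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(10)])
    adj = spearman_screen(frame, top_k=6, alpha=0.05, adjust="bh").pairs
    assert (adj["p_adjusted"] >= adj["p_raw"] - 1e-15).all()
    assert (adj["p_adjusted"] <= 1.0).all()
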