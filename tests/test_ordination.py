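import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from cecofec.core_tables import TableError, build_paired_design
from cecofec.css import css_normalize
from cecofec.ordination import (
    paired_pca,
    pcoa,
    weighted_unifrac,
    within_animal_deviations,
)
from cecofec.synthetic import SyntheticParams, generate_dataset, generate_random_tree


def brute_force_unifrac(df, tree, normalize=False):
    """Independent oracle: explicit per-branch tip-set accumulation."""
    samples = list(df.index)
    totals = df.sum(axis=1)
    out = np.zeros((len(samples), len(samples)))
    branches = []
    for node in tree.traverse(include_self=False):
        if node.length:
            tips = {t.name for t in node.tips()} or {node.name}
            branches.append((float(node.length), tips))
    for i, a in enumerate(samples):
        for j, b in enumerate(samples):
            d = 0.0
            denom = 0.0
            for length, tips in branches:
                pa = sum(df.loc[a, t] for t in tips if t in df.columns) / totals[a]
                pb = sum(df.loc[b, t] for t in tips if t in df.columns) / totals[b]
                d += length * abs(pa - pb)
                denom += length * (pa + pb)
            out[i, j] = d / denom if (normalize and denom > 0) else d
    return out


def test_two_tip_hand_example():
    tree = TreeNode.read(io.StringIO("(t1:1,t2:2):0;"))
    df = pd.DataFrame([[5, 0], [0, 7]], index=["A", "B"], columns=["t1", "t2"])
    dm = weighted_unifrac(df, tree)
    assert dm["A", "B"] == pytest.approx(3.0)
    assert dm["A", "A"] == 0.0


def test_identical_profiles_have_zero_distance():
    tree = generate_random_tree([f"o{i}" for i in range(6)], seed=1)
    row = np.array([1.0, 2, 0, 4, 0, 3])
    df = pd.DataFrame([row, 5 * row], index=["A", "B"], columns=[f"o{i}" for i in range(6)])
    dm = weighted_unifrac(df, tree)
    # scaling a sample's abundances changes nothing (proportions only)
    assert dm["A", "B"] == pytest.approx(0.0, abs=1e-12)


def test_unifrac_matches_brute_force_on_random_trees():
    rng = np.random.default_rng(21)
    for rep in range(100):
        n_tips = int(rng.integers(2, 9))
        ids = [f"o{i}" for i in range(n_tips)]
        tree = generate_random_tree(ids, seed=int(rng.integers(2**31)))
        counts = rng.integers(0, 20, size=(3, n_tips)).astype(float)
        counts[:, 0] += 1  # positive totals
        df = pd.DataFrame(counts, index=["A", "B", "C"], columns=ids)
        for normalize in (False, True):
            dm = weighted_unifrac(df, tree, normalize_branch=normalize)
            expected = brute_force_unifrac(df, tree, normalize=normalize)
            np.testing.assert_allclose(dm.data, expected, atol=1e-10)


def test_unifrac_matches_scikit_bio_on_integer_counts():
    from skbio.diversity import beta_diversity

    rng = np.random.default_rng(3)
    ids = [f"o{i}" for i in range(12)]
    tree = generate_random_tree(ids, seed=8)
    counts = rng.integers(0, 50, size=(5, 12))
    counts[:, 0] += 1
    samples = [f"s{i}" for i in range(5)]
    df = pd.DataFrame(counts, index=samples, columns=ids)
    ours = weighted_unifrac(df, tree)
    theirs = beta_diversity("weighted_unifrac", counts, ids=samples, taxa=ids, tree=tree)
    np.testing.assert_allclose(ours.data, theirs.data, atol=1e-10)


def test_unifrac_missing_otu_named():
    tree = generate_random_tree(["a", "b"], seed=0)
    df = pd.DataFrame([[1, 2, 3]], index=["s"], columns=["a", "b", "ghost"])
    with pytest.raises(TableError, match="ghost"):
        weighted_unifrac(df, tree)


def test_pcoa_recovers_euclidean_configuration():
    rng = np.random.default_rng(4)
    points = rng.normal(size=(20, 3))
    D = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    res = pcoa(D)
    coords = res.coordinates.to_numpy()
    D_hat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.testing.assert_allclose(D_hat, D, atol=1e-9)
    assert res.eigenvalues.min() > -1e-9  # Euclidean-embeddable input
    assert np.all(np.diff(res.eigenvalues) <= 1e-9)


def test_pcoa_two_points_and_duplicates():
    res = pcoa(np.array([[0.0, 4.0], [4.0, 0.0]]))
    np.testing.assert_allclose(np.abs(res.coordinates.to_numpy()[:, 0]), 2.0)
    # duplicated point collapses onto the same coordinates
    D = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
    res2 = pcoa(D)
    c = res2.coordinates.to_numpy()
    np.testing.assert_allclose(c[0], c[2], atol=1e-9)


def test_pcoa_rejects_asymmetry():
    with pytest.raises(TableError, match="asymmetric"):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_within_deviations_rows_and_ss_decomposition(small_dataset):
    design = small_dataset["design"]
    norm = css_normalize(small_dataset["table"], quantile=0.5)
    W = within_animal_deviations(norm, design)
    n = design.n_animals
    # each animal's two rows cancel
    np.testing.assert_allclose(W.matrix[:n] + W.matrix[n:], 0.0, atol=1e-12)
    # total SS about the grand profile = within SS + between-animal SS
    X = norm.to_dataframe().loc[list(design.sample_ids())].to_numpy()
    grand = X.mean(axis=0)
    total_ss = ((X - grand) ** 2).sum()
    within_ss = (W.matrix**2).sum()
    pair_means = (X[:n] + X[n:]) / 2.0
    between_ss = 2.0 * ((pair_means - grand) ** 2).sum()
    assert within_ss + between_ss == pytest.approx(total_ss, rel=1e-9)


def test_within_deviations_hand_example():
    df = pd.DataFrame([[4.0], [2.0]], index=["A0_C", "A0_F"], columns=["o1"])
    from conftest import make_design

    W = within_animal_deviations(df, make_design(1))
    np.testing.assert_allclose(W.matrix, [[1.0], [-1.0]])


def test_paired_pca_reconstruction_and_symmetry(small_dataset):
    design = small_dataset["design"]
    norm = css_normalize(small_dataset["table"], quantile=0.5)
    W = within_animal_deviations(norm, design)
    full = paired_pca(W, n_components=4)
    assert np.all(np.diff(full.eigenvalues) <= 1e-6)
    # full reconstruction of the centered matrix
    X = W.matrix - W.matrix.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    np.testing.assert_allclose((U * s) @ Vt, X, atol=1e-9)
    # pair scores mirror through the origin once the column means vanish:
    # within rows already sum to zero across the pair, and with the full
    # paired block design the column means of W are exactly zero
    np.testing.assert_allclose(W.matrix.mean(axis=0), 0.0, atol=1e-12)
    n = design.n_animals
    scores = full.coordinates.to_numpy()
    np.testing.assert_allclose(scores[:n], -scores[n:], atol=1e-6)


def test_paired_pca_truncates_beyond_rank():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(1, 6))
    from cecofec.ordination import WithinMatrix

    M = np.vstack([base, -base])  # rank 1
    W = WithinMatrix(M, ("a_C", "a_F"), tuple(f"o{i}" for i in range(6)), ("a", "a"))
    with pytest.warns(UserWarning, match="rank"):
        res = paired_pca(W, n_components=4)
    assert res.coordinates.shape[1] == 1
    assert res.proportion_explained[0] == pytest.approx(1.0)
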