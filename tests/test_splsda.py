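import numpy as np
import pandas as pd
import pytest

from cecofec.core_tables import TableError, build_paired_design
from cecofec.css import css_normalize
from cecofec.ordination import within_animal_deviations
from cecofec.splsda import explained_variance, feature_contributions, fit_splsda
from cecofec.synthetic import SyntheticParams, generate_dataset, paired_noise_sd


def nipals_plsda(X, Y, n_components, tol=1e-12, max_iter=2000):
    """Independent dense PLS2 oracle: classic NIPALS score-exchange loop
    with regression-mode deflation of X and Y."""
    Xh = X - X.mean(axis=0)
    Xh = Xh / Xh.std(axis=0, ddof=1)
    Yh = Y - Y.mean(axis=0)
    variates = []
    for _ in range(n_components):
        u_score = Yh[:, [int(np.argmax(Yh.var(axis=0)))]]
        w = np.zeros((X.shape[1], 1))
        for _ in range(max_iter):
            w_new = Xh.T @ u_score
            w_new /= np.linalg.norm(w_new)
            t_score = Xh @ w_new
            q = Yh.T @ t_score / (t_score.T @ t_score).item()
            u_new = Yh @ q / (q.T @ q).item()
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u_score = w_new, u_new
        t_score = Xh @ w
        variates.append(t_score.ravel())
        p_load = Xh.T @ t_score / (t_score.T @ t_score).item()
        c_load = Yh.T @ t_score / (t_score.T @ t_score).item()
        Xh = Xh - t_score @ p_load.T
        Yh = Yh - t_score @ c_load.T
    return np.column_stack(variates)


def random_labels_design(n, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 10))
    labels = np.array(["cecum", "feces"] * (n // 2))
    return X, labels


def test_exact_keepx_support_and_unit_norm():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(16, 25))
    labels = np.array(["cecum", "feces"] * 8)
    model = fit_splsda(X, labels, keepx=(7, 3), scale=True)
    for h, k in enumerate((7, 3)):
        col = model.x_loadings.iloc[:, h].to_numpy()
        assert np.count_nonzero(col) == k
        assert np.linalg.norm(col) == pytest.approx(1.0, abs=1e-9)


def test_penalty_free_limit_matches_dense_nipals():
    """keepX = p reproduces a dense NIPALS PLS-DA (variates to 1e-6, signs
    aligned)."""
    X, labels = random_labels_design(20, seed=1)
    Y = np.column_stack([(labels == c).astype(float) for c in ("cecum", "feces")])
    model = fit_splsda(X, labels, keepx=(10, 10), scale=True)
    expected = nipals_plsda(X, Y, 2)
    got = model.x_variates.to_numpy()
    for h in range(2):
        sign = np.sign(got[:, h] @ expected[:, h])
        np.testing.assert_allclose(got[:, h], sign * expected[:, h], atol=1e-6)


def test_successive_variates_orthogonal():
    X, labels = random_labels_design(20, seed=2)
    model = fit_splsda(X, labels, keepx=(6, 6), scale=True)
    t1, t2 = model.x_variates.to_numpy().T
    assert abs(t1 @ t2) / (np.linalg.norm(t1) * np.linalg.norm(t2)) < 1e-6


def test_single_informative_feature_is_selected():
    labels = np.array(["cecum", "feces"] * 10)
    rng = np.random.default_rng(3)
    X = rng.normal(0, 0.01, size=(20, 8))
    X[:, 5] += np.where(labels == "cecum", 1.0, -1.0)
    model = fit_splsda(X, labels, keepx=(1,), scale=False)
    assert model.selected_features(1) == ("f5",)


def test_feature_order_permutation_permutes_loadings():
    X, labels = random_labels_design(20, seed=4)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(10)])
    m1 = fit_splsda(df, labels, keepx=(4,), scale=True)
    perm = list(df.columns[::-1])
    m2 = fit_splsda(df[perm], labels, keepx=(4,), scale=True)
    l1 = m1.x_loadings.iloc[:, 0]
    l2 = m2.x_loadings.iloc[:, 0].reindex(l1.index)
    sign = np.sign(l1.to_numpy() @ l2.to_numpy()) or 1.0
    np.testing.assert_allclose(l1.to_numpy(), sign * l2.to_numpy(), atol=1e-9)


def test_keepx_larger_than_p_errors_and_constant_feature_named():
    X, labels = random_labels_design(10, seed=5)
    with pytest.raises(TableError, match="keepX"):
        fit_splsda(X, labels, keepx=(11,), scale=False)
    X[:, 2] = 1.0
    with pytest.raises(TableError, match="f2"):
        fit_splsda(X, labels, keepx=(3,), scale=True)


def test_explained_variance_bounds_and_oracle():
    X, labels = random_labels_design(20, seed=6)
    model = fit_splsda(X, labels, keepx=(10, 10), scale=True)
    fractions = explained_variance(model, X)
    assert np.all(fractions >= 0) and np.all(fractions <= 1)
    assert fractions.sum() <= 1 + 1e-9
    # residual-SS oracle: explained fraction = 1 - RSS/TSS after deflation
    Xc = X - X.mean(axis=0)
    Xc = Xc / Xc.std(axis=0, ddof=1)
    total = (Xc**2).sum()
    Xh = Xc.copy()
    for h in range(2):
        xi = Xh @ model.x_loadings.iloc[:, h].to_numpy()
        Xh = Xh - np.outer(xi, Xh.T @ xi / (xi @ xi))
    assert fractions.sum() == pytest.approx(1 - (Xh**2).sum() / total, rel=1e-9)


def test_exact_low_rank_data_fully_explained():
    rng = np.random.default_rng(7)
    t = rng.normal(size=(12, 1))
    X = t @ rng.normal(size=(1, 5))
    labels = np.array(["cecum", "feces"] * 6)
    model = fit_splsda(X, labels, keepx=(5,), scale=False)
    assert explained_variance(model, X)[0] == pytest.approx(1.0, rel=1e-9)


def _planted_run(seed, n_animals=50, n_otus=100, keepx=(20,)):
    eff = 1.5 * paired_noise_sd(10.0)
    params = SyntheticParams(n_animals=n_animals, n_otus=n_otus,
                             frac_differential=0.2, origin_effect_size=eff,
                             seed=seed)
    table, meta, *_, truth = generate_dataset(params)
    design = build_paired_design(meta, table)
    norm = css_normalize(table, quantile=0.5)
    W = within_animal_deviations(norm, design)
    labels = [meta[s].origin for s in W.sample_ids]
    model = fit_splsda(W, labels, keepx, scale=True)
    return model, W, labels, truth


def test_planted_features_recovered_on_component_one():
    recoveries = []
    for seed in range(5):
        model, _, _, truth = _planted_run(seed)
        sel = set(model.selected_features(1))
        recoveries.append(len(sel & truth.differential_otu_ids))
    assert np.median(recoveries) >= 16  # of 20 planted


def test_contribution_class_matches_true_effect_sign():
    model, W, labels, truth = _planted_run(0)
    contrib = feature_contributions(model, W, labels).query("component == 1")
    checked, correct = 0, 0
    for _, row in contrib.iterrows():
        delta = truth.log_fold_effects.get(row["feature"], 0.0)
        if delta == 0.0:
            continue
        checked += 1
        expected = "cecum" if delta > 0 else "feces"
        correct += row["class"] == expected
    assert checked > 0
    assert correct / checked >= 0.9


def test_global_label_swap_flips_assignments():
    model, W, labels, _ = _planted_run(1)
    swapped = ["feces" if l == "cecum" else "cecum" for l in labels]
    c1 = feature_contributions(model, W, labels)
    c2 = feature_contributions(model, W, swapped)
    merged = c1.merge(c2, on=["component", "feature"], suffixes=("_a", "_b"))
    assert (merged["class_a"] != merged["class_b"]).all()
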