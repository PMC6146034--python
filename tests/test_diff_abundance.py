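import numpy as np
import pandas as pd
import pytest

from conftest import make_design, paired_values
from cecofec.core_tables import PairedDesign, TableError, build_paired_design
from cecofec.css import css_normalize
from cecofec.diff_abundance import (
    BootstrapConfig,
    bh_fdr,
    bootstrap_p,
    paired_f_statistic,
    run_diff_abundance,
)
from cecofec.synthetic import SyntheticParams, generate_dataset


def test_degenerate_certainty_gives_infinite_f():
    design = make_design(4)
    vals = paired_values([3, 3, 3, 3], [1, 1, 1, 1])  # d = (2,2,2,2)
    F, diff, se = paired_f_statistic(vals, design)
    assert np.isinf(F) and diff == 2.0 and se == 0.0


def test_null_identity_gives_zero_f():
    design = make_design(5)
    vals = paired_values([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    F, diff, se = paired_f_statistic(vals, design)
    assert F == 0.0 and diff == 0.0


def test_f_equals_extra_sum_of_squares_from_linear_model():
    """n*mean(d)^2/var(d) equals the extra-SS F for origin in the
    animal + origin least-squares fit, on 100 random instances."""
    rng = np.random.default_rng(12)
    for _ in range(100):
        n = int(rng.integers(3, 15))
        cecum = rng.normal(0, 1, n)
        feces = rng.normal(0, 1, n)
        design = make_design(n)
        F, _, _ = paired_f_statistic(paired_values(cecum, feces), design)

        # independent oracle: explicit design-matrix fits
        y = np.concatenate([cecum, feces])
        animal = np.tile(np.eye(n), (2, 1))
        origin = np.concatenate([np.ones(n), np.zeros(n)])[:, None]
        X_full = np.hstack([animal, origin])
        X_red = animal
        rss = lambda X: float(
            ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
        )
        df_resid = 2 * n - (n + 1)
        F_lm = (rss(X_red) - rss(X_full)) / (rss(X_full) / df_resid)
        assert F == pytest.approx(F_lm, rel=1e-9, abs=1e-9)


def test_bootstrap_p_extremes_and_determinism():
    design = make_design(6)
    cfg = BootstrapConfig(B=500, seed=3)
    null_vals = paired_values([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
    with pytest.warns(UserWarning):
        assert bootstrap_p(null_vals, design, cfg) == 1.0  # all d = 0
    rng = np.random.default_rng(1)
    vals = paired_values(rng.normal(1, 1, 6), rng.normal(0, 1, 6))
    p1 = bootstrap_p(vals, design, cfg)
    p2 = bootstrap_p(vals, design, cfg)
    assert p1 == p2
    assert 0.0 <= p1 <= 1.0


def test_zero_f_has_p_one():
    # d has exact mean 0 and positive variance -> F_obs = 0, every F* >= 0
    design = make_design(4)
    vals = paired_values([1, -1, 2, -2], [0, 0, 0, 0])
    assert bootstrap_p(vals, design, BootstrapConfig(B=200, seed=0)) == 1.0


def test_add_one_rule_never_returns_zero():
    design = make_design(10)
    rng = np.random.default_rng(2)
    vals = paired_values(rng.normal(5, 0.1, 10), rng.normal(0, 0.1, 10))
    cfg = BootstrapConfig(B=100, seed=0, p_rule="add_one")
    p = bootstrap_p(vals, design, cfg)
    assert p >= 1 / 101


def test_null_bootstrap_p_is_calibrated():
    """Under a true null, p <= 0.05 for about 5% of features."""
    rng = np.random.default_rng(7)
    n, n_features, B = 21, 500, 1000
    design = make_design(n)
    cfg = BootstrapConfig(B=B, seed=7)
    hits = 0
    for k in range(n_features):
        vals = paired_values(rng.normal(size=n), rng.normal(size=n))
        if bootstrap_p(vals, design, cfg, feature_id=f"f{k}") <= 0.05:
            hits += 1
    rate = hits / n_features
    mc_se = np.sqrt(0.05 * 0.95 / n_features)
    assert abs(rate - 0.05) <= 2.5 * mc_se


def test_bh_hand_example_and_edge_cases():
    np.testing.assert_allclose(
        bh_fdr([0.01, 0.02, 0.04, 0.5]), [0.04, 0.04, 0.16 / 3, 0.5], rtol=1e-12
    )
    np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    np.testing.assert_allclose(bh_fdr([0.123]), [0.123])
    with pytest.raises(TableError):
        bh_fdr([0.5, 1.2])


def test_label_swap_symmetry():
    """Swapping cecum and feces globally flips the sign of the difference
    but leaves F and the bootstrap p unchanged."""
    p = SyntheticParams(n_animals=9, n_otus=30, frac_differential=0.3,
                        origin_effect_size=1.0, seed=13)
    table, meta, *_ = generate_dataset(p)
    design = build_paired_design(meta, table)
    swapped = PairedDesign(
        tuple((a, f, c) for a, c, f in design.pairs), design.animal_regime
    )
    norm = css_normalize(table, quantile=0.5)
    cfg = BootstrapConfig(B=300, seed=5)
    r1 = run_diff_abundance(norm, design, cfg)
    r2 = run_diff_abundance(norm, swapped, cfg)
    np.testing.assert_allclose(r1.table["difference"], -r2.table["difference"], rtol=1e-12)
    np.testing.assert_allclose(r1.table["F"], r2.table["F"], rtol=1e-12)
    np.testing.assert_allclose(r1.table["p_boot"], r2.table["p_boot"], rtol=1e-12)


def test_results_independent_of_feature_order(small_dataset):
    design = small_dataset["design"]
    norm = css_normalize(small_dataset["table"], quantile=0.5)
    cfg = BootstrapConfig(B=200, seed=9)
    df = norm.to_dataframe()
    r1 = run_diff_abundance(df, design, cfg)
    r2 = run_diff_abundance(df[df.columns[::-1]], design, cfg)
    common = sorted(df.columns)
    np.testing.assert_allclose(
        r1.table.loc[common, "p_boot"], r2.table.loc[common, "p_boot"], rtol=1e-12
    )


def test_planted_effects_are_recovered(small_dataset):
    table = small_dataset["table"]
    truth = small_dataset["truth"]
    design = small_dataset["design"]
    norm = css_normalize(table, quantile=0.5)
    res = run_diff_abundance(norm, design, BootstrapConfig(B=500, seed=2))
    sig = set(res.significant_features())
    if sig:
        # significant set should be enriched for truly differential OTUs
        frac_true_in_sig = len(sig & truth.differential_otu_ids) / len(sig)
        frac_true_overall = len(truth.differential_otu_ids) / table.n_otus
        assert frac_true_in_sig > frac_true_overall
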