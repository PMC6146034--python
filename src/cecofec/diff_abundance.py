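"""Paired bootstrap-F differential abundance test with BH-FDR control.

For one feature (an OTU's CSS abundance, or a taxon's relative abundance)
with paired samples, let d_i = cecum_i - feces_i over the n animals.  The
origin effect is mean(d) with standard error sd(d)/sqrt(n), and its F
statistic is

    F_obs = n * mean(d)^2 / var(d)

which equals the extra-sum-of-squares F for the origin term in the
animal + origin linear model (the feeding regime, being constant within
animal, is absorbed by the animal block and does not alter the test).
Instead of referring F_obs to a theoretical F distribution, an empirical
null is built by resampling the centered differences {d_i - mean(d)} with
replacement; the p-value is the proportion of resamples whose F statistic
is equal to or greater than F_obs.  P-values across features are then
corrected by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from cecofec.core_tables import PairedDesign, TableError

__all__ = [
    "BootstrapConfig",
    "DiffAbundanceResult",
    "paired_f_statistic",
    "bootstrap_p",
    "bh_fdr",
    "run_diff_abundance",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap-test settings: B resamples, FDR level, seed, p-value rule.

    ``p_rule`` "proportion" is the literal definition #{F* >= F_obs}/B;
    "add_one" uses (# + 1)/(B + 1) to avoid zero p-values.
    """

    B: int = 1000
    alpha_fdr: float = 0.05
    seed: int = 0
    p_rule: str = "proportion"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise TableError("B must be >= 1")
        if not 0.0 < self.alpha_fdr < 1.0:
            raise TableError("alpha_fdr must be in (0, 1)")
        if self.p_rule not in ("proportion", "add_one"):
            raise TableError(f"unknown p_rule {self.p_rule!r}")


@dataclass(frozen=True)
class DiffAbundanceResult:
    """Per-feature results of one differential-abundance run.

    ``table`` has one row per feature: per-origin mean and SD, the
    cecum - feces difference and its SE, F_obs, bootstrap p, BH q and the
    significance call at ``config.alpha_fdr``.  Positive differences mean
    overrepresentation in cecum.
    """

    table: pd.DataFrame
    config: BootstrapConfig
    level: str = "otu"

    def significant_features(self) -> tuple[str, ...]:
        return tuple(self.table.index[self.table["significant"]])


def _paired_differences(values, design: PairedDesign) -> np.ndarray:
    cecum = np.array([values[s] for s in design.cecum_samples], dtype=float)
    feces = np.array([values[s] for s in design.feces_samples], dtype=float)
    return cecum - feces


def _f_from_d(d: np.ndarray) -> float:
    n = d.size
    v = d.var(ddof=1)
    m = d.mean()
    if v == 0.0:
        return 0.0 if m == 0.0 else np.inf
    return n * m * m / v


def paired_f_statistic(values, design: PairedDesign) -> tuple[float, float, float]:
    """(F_obs, cecum - feces difference, SE) for one feature.

    Zero variance of the differences with a nonzero mean yields F = +inf
    (degenerate certainty); all-zero differences yield F = 0.
    """
    d = _paired_differences(values, design)
    n = d.size
    if n < 2:
        raise TableError("paired F statistic needs at least 2 pairs")
    se = float(d.std(ddof=1) / np.sqrt(n))
    return float(_f_from_d(d)), float(d.mean()), se


def _feature_rng(seed: int, feature_id: str) -> np.random.Generator:
    # keyed on the feature id, not its position, so results do not depend
    # on feature order
    return np.random.default_rng([seed, zlib.crc32(str(feature_id).encode())])


def bootstrap_p(values, design: PairedDesign, cfg: BootstrapConfig,
                feature_id: str = "feature") -> float:
    """Empirical bootstrap p-value for one feature's origin effect.

    Resamples the centered differences {d_i - mean(d)} with replacement B
    times and counts resamples whose F statistic is >= F_obs (ties count).
    """
    d = _paired_differences(values, design)
    f_obs = _f_from_d(d)
    return _bootstrap_p_from_d(d, f_obs, cfg, feature_id)


def _bootstrap_p_from_d(d: np.ndarray, f_obs: float, cfg: BootstrapConfig,
                        feature_id: str) -> float:
    n = d.size
    if d.var(ddof=1) == 0.0:
        p = 1.0 if np.all(d == 0.0) else 0.0
        warnings.warn(
            f"feature {feature_id!r}: zero variance of paired differences; p set to {p}",
            stacklevel=2,
        )
        return p
    rng = _feature_rng(cfg.seed, feature_id)
    centered = d - d.mean()
    idx = rng.integers(0, n, size=(cfg.B, n))
    resamples = centered[idx]
    means = resamples.mean(axis=1)
    variances = resamples.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = n * means**2 / variances
    f_star = np.where(variances == 0.0, np.where(means == 0.0, 0.0, np.inf), f_star)
    hits = int(np.count_nonzero(f_star >= f_obs))
    if cfg.p_rule == "add_one":
        return (hits + 1) / (cfg.B + 1)
    return hits / cfg.B


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise TableError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_diff_abundance(table, design: PairedDesign, cfg: BootstrapConfig,
                       level: str = "otu") -> DiffAbundanceResult:
    """Run the paired bootstrap-F test on every feature of a table.

    ``table`` is a CSS :class:`~cecofec.css.NormalizedTable` (OTU level) or
    a :class:`~cecofec.taxonomy.RankTable` (genus/phylum level); anything
    with ``to_dataframe()`` returning samples x features works.  Features
    are expected to be pre-filtered (e.g. >= 5% prevalence at OTU level).
    Each feature uses an RNG substream keyed on the feature id, so the
    result is independent of feature order.
    """
    df = table if isinstance(table, pd.DataFrame) else table.to_dataframe()
    rows = []
    for feature in df.columns:
        values = df[feature]
        cecum = values.loc[list(design.cecum_samples)].to_numpy(dtype=float)
        feces = values.loc[list(design.feces_samples)].to_numpy(dtype=float)
        d = cecum - feces
        f_obs = _f_from_d(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = _bootstrap_p_from_d(d, f_obs, cfg, feature)
        rows.append(
            {
                "feature": feature,
                "cecum_mean": cecum.mean(),
                "cecum_sd": cecum.std(ddof=1),
                "feces_mean": feces.mean(),
                "feces_sd": feces.std(ddof=1),
                "difference": d.mean(),
                "se": d.std(ddof=1) / np.sqrt(d.size),
                "F": f_obs,
                "p_boot": p,
            }
        )
    result = pd.DataFrame(rows).set_index("feature")
    result["q"] = bh_fdr(result["p_boot"].to_numpy())
    result["significant"] = result["q"] <= cfg.alpha_fdr
    return DiffAbundanceResult(result, cfg, level)
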