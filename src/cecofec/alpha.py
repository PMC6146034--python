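"""Rarefied alpha diversity and its paired analysis of variance.

Samples are rarefied (subsampled without replacement) to a common depth,
Shannon diversity (base 2 by default) and observed OTU richness are
computed, and each index is analysed with a paired ANOVA whose factors are
the sampling origin (cecum/feces), the origin x feeding-regime
interaction, and the animal block.  The regime main effect is confounded
with the animal and is therefore reported from a between-animal model on
animal means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cecofec.core_tables import OtuTable, PairedDesign, TableError

__all__ = [
    "rarefy",
    "shannon",
    "observed_otus",
    "alpha_diversity",
    "alpha_paired_anova",
    "AlphaAnovaResult",
]


def rarefy(sample_counts, depth: int, seed: int, sample_id: str = "<sample>") -> np.ndarray:
    """Subsample exactly ``depth`` reads without replacement.

    Deterministic given ``seed``.  Raises if the sample holds fewer than
    ``depth`` reads, naming the offending sample.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise TableError(
            f"sample {sample_id!r} has {total} reads, fewer than rarefaction depth {depth}"
        )
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(seed)
    # draw read indices without replacement; map back to OTUs via cumsum bins
    chosen = rng.choice(total, size=depth, replace=False)
    edges = np.cumsum(counts)
    otu_of_read = np.searchsorted(edges, chosen, side="right")
    return np.bincount(otu_of_read, minlength=counts.size).astype(np.int64)


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise TableError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_otus(counts) -> int:
    """Number of OTUs with at least one read."""
    return int((np.asarray(counts) > 0).sum())


def alpha_diversity(
    table: OtuTable,
    depth: int,
    seed: int,
    n_draws: int = 1,
    shannon_base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample rarefied indices.

    One rarefaction draw per sample by default (per-sample substreams
    derived from ``seed`` and the sample's position, so a seed pins the
    result); ``n_draws > 1`` averages the indices over repeated draws.
    """
    rows = []
    for j, sid in enumerate(table.sample_ids):
        obs, sh = 0.0, 0.0
        for r in range(n_draws):
            sub = rarefy(table.counts[j], depth, seed=np.random.default_rng([seed, j, r]).integers(2**31), sample_id=sid)
            obs += observed_otus(sub)
            sh += shannon(sub, base=shannon_base)
        rows.append({"sample_id": sid, "observed_otus": obs / n_draws, "shannon": sh / n_draws})
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class AlphaAnovaResult:
    """Paired-ANOVA summary for one alpha index.

    ``terms`` maps origin / regime / origin_x_regime to (F, df1, df2, p);
    ``group_stats`` holds observed means and SDs per origin, overall and
    within regime.
    """

    terms: dict[str, tuple[float, int, int, float]]
    group_stats: pd.DataFrame
    index_name: str = ""


def _ls_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def alpha_paired_anova(values: pd.Series, design: PairedDesign,
                       include_interaction: bool = True) -> AlphaAnovaResult:
    """Paired ANOVA of one alpha index.

    Fits index ~ animal + origin (+ origin x regime) by least squares with
    centered +-1/2 codings for origin and regime; origin and interaction
    are tested against the residual mean square with n_animals - 2 residual
    degrees of freedom.  The regime main effect, confounded with the
    animal, is tested between animals on animal means (df = n_animals - 2).
    Without the interaction term, F(origin) equals the squared paired t
    statistic on within-animal differences.
    """
    n = design.n_animals
    if n < 3:
        raise TableError("paired ANOVA needs at least 3 animals for residual df")
    cecum = np.array([values[s] for s in design.cecum_samples], dtype=float)
    feces = np.array([values[s] for s in design.feces_samples], dtype=float)
    y = np.concatenate([cecum, feces])
    origin_c = np.concatenate([np.full(n, 0.5), np.full(n, -0.5)])
    regime = np.array([design.animal_regime[a] for a in design.animal_ids])
    regime_c = np.where(regime == "restricted", 0.5, -0.5)
    regime_full = np.concatenate([regime_c, regime_c])
    if len(set(regime)) < 2:
        include_interaction = False  # collinear with origin in a one-regime design
    animal_dummies = np.zeros((2 * n, n - 1))
    for i in range(n - 1):
        animal_dummies[i, i] = 1.0
        animal_dummies[n + i, i] = 1.0

    blocks = [np.ones((2 * n, 1)), animal_dummies, origin_c[:, None]]
    if include_interaction:
        blocks.append((origin_c * regime_full)[:, None])
    X_full = np.hstack(blocks)
    df_resid = 2 * n - X_full.shape[1]
    rss_full = _ls_rss(X_full, y)
    # a numerically perfect fit must behave as zero residual variance
    y_scale = float(((y - y.mean()) ** 2).sum()) + 1.0
    if rss_full <= 1e-12 * y_scale:
        rss_full = 0.0
    ms_resid = rss_full / df_resid

    terms: dict[str, tuple[float, int, int, float]] = {}

    def add_term(name: str, drop_col: int) -> None:
        X_red = np.delete(X_full, drop_col, axis=1)
        extra = max(_ls_rss(X_red, y) - rss_full, 0.0)
        if extra <= 1e-12 * y_scale:
            extra = 0.0
        if ms_resid > 0:
            F = extra / ms_resid
            p = float(stats.f.sf(F, 1, df_resid))
        else:
            F = np.inf if extra > 0 else 0.0
            p = 0.0 if extra > 0 else 1.0
        terms[name] = (float(F), 1, df_resid, p)

    origin_col = 1 + (n - 1)
    add_term("origin", origin_col)
    if include_interaction:
        add_term("origin_x_regime", origin_col + 1)

    # between-animal regime test on animal means
    means = (cecum + feces) / 2.0
    Xb_full = np.hstack([np.ones((n, 1)), regime_c[:, None]])
    rss_b_full = _ls_rss(Xb_full, means)
    rss_b_red = _ls_rss(np.ones((n, 1)), means)
    df_b = n - 2
    ms_b = rss_b_full / df_b
    Fb = (rss_b_red - rss_b_full) / ms_b if ms_b > 0 else 0.0
    terms["regime"] = (float(Fb), 1, df_b, float(stats.f.sf(Fb, 1, df_b)))

    rows = []
    for label, mask in [
        ("restricted", regime == "restricted"),
        ("ad_libitum", regime == "ad_libitum"),
        ("average", np.ones(n, dtype=bool)),
    ]:
        if not mask.any():
            continue
        c, f = cecum[mask], feces[mask]
        d = c - f
        if mask.sum() >= 2 and d.std(ddof=1) > 0:
            t_p = float(stats.ttest_rel(c, f).pvalue)
        else:
            t_p = 1.0 if np.allclose(d, 0) else 0.0
        rows.append(
            {
                "regime": label,
                "cecum_mean": c.mean(),
                "cecum_sd": c.std(ddof=1) if len(c) > 1 else 0.0,
                "feces_mean": f.mean(),
                "feces_sd": f.std(ddof=1) if len(f) > 1 else 0.0,
                "p_paired": t_p,
            }
        )
    group_stats = pd.DataFrame(rows).set_index("regime")
    return AlphaAnovaResult(terms, group_stats, index_name=str(values.name or ""))
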