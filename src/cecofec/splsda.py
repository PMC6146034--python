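"""Multilevel sparse PLS discriminant analysis (sPLS-DA).

PLS-DA regresses a one-hot class indicator matrix Y on the feature matrix
X by maximizing covariance between their latent variates; the sparse
variant additionally LASSO-shrinks each component's X-loading vector so
that only a fixed number (keepX) of features contribute.  Applied to the
within-animal deviation matrix of a paired design, component 1 extracts
the combination of OTUs that best separates cecal from fecal samples
inside each animal.

Per component h: the leading singular pair (u, v) of M = X_h' Y_h is found
by power iteration (started from the column of M with the largest norm,
so the fit is deterministic); u is soft-thresholded so that exactly
keepX_h entries survive (the largest magnitudes, ties broken by feature
order) and renormalized; variates are xi = X_h u and omega = Y_h v; both
X and Y are deflated by regressing them on xi (regression mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cecofec.core_tables import TableError
from cecofec.ordination import WithinMatrix

__all__ = ["SplsdaModel", "fit_splsda", "feature_contributions", "explained_variance"]


@dataclass(frozen=True)
class SplsdaModel:
    """Fitted sparse PLS-DA model.

    ``x_loadings`` (features x components) have unit norm with exactly
    ``keepx[h]`` nonzeros in column h; ``x_variates`` are the sample
    scores xi_h.  ``explained_x_variance`` is each component's share of
    the (centered, optionally scaled) X sum of squares.
    """

    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    x_variates: pd.DataFrame
    y_variates: pd.DataFrame
    keepx: tuple[int, ...]
    classes: tuple[str, ...]
    explained_x_variance: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    scaled: bool

    @property
    def n_components(self) -> int:
        return len(self.keepx)

    def selected_features(self, component: int = 1) -> tuple[str, ...]:
        """Feature ids with nonzero loading on ``component`` (1-based)."""
        col = self.x_loadings.iloc[:, component - 1]
        return tuple(col.index[col != 0.0])


def _as_matrix(W) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(W, WithinMatrix):
        return W.matrix.astype(float), list(W.sample_ids), list(W.otu_ids)
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(dtype=float), list(W.index), list(W.columns)
    X = np.asarray(W, dtype=float)
    return X, [f"s{i}" for i in range(X.shape[0])], [f"f{j}" for j in range(X.shape[1])]


def _preprocess(X: np.ndarray, feature_ids, scale: bool):
    means = X.mean(axis=0)
    Xc = X - means
    if scale:
        sds = Xc.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [feature_ids[j] for j in np.flatnonzero(sds == 0)[:5]]
            raise TableError(f"constant features cannot be unit-scaled: {bad}")
        Xc = Xc / sds
    else:
        sds = np.ones(X.shape[1])
    return Xc, means, sds


def _leading_singular_pair(M: np.ndarray, tol: float = 1e-12, max_iter: int = 1000):
    """Dominant singular pair of M by power iteration, deterministic start."""
    start = int(np.argmax(np.linalg.norm(M, axis=0)))
    u = M[:, start]
    nrm = np.linalg.norm(u)
    if nrm == 0:
        u = np.zeros(M.shape[0])
        u[0] = 1.0
        return u, np.zeros(M.shape[1])
    u = u / nrm
    v = np.zeros(M.shape[1])
    for _ in range(max_iter):
        v_new = M.T @ u
        v_new /= max(np.linalg.norm(v_new), np.finfo(float).tiny)
        u_new = M @ v_new
        u_new /= max(np.linalg.norm(u_new), np.finfo(float).tiny)
        if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
            u, v = u_new, v_new
            break
        u, v = u_new, v_new
    return u, v


def _soft_threshold_exact(u: np.ndarray, keepx: int) -> np.ndarray:
    """Soft-threshold keeping exactly ``keepx`` nonzero entries.

    The threshold is the largest excluded magnitude; ranking ties are
    broken by feature order, and a surviving entry tied with the threshold
    keeps a vanishing but nonzero magnitude so the support size is exact.
    """
    p = u.size
    if keepx > p:
        raise TableError(f"keepX={keepx} exceeds number of features {p}")
    mag = np.abs(u)
    order = np.lexsort((np.arange(p), -mag))
    selected = order[:keepx]
    lam = mag[order[keepx]] if keepx < p else 0.0
    out = np.zeros(p)
    shrunk = mag[selected] - lam
    tiny = np.finfo(float).tiny
    shrunk = np.where(shrunk > 0, shrunk, mag[selected] * 1e-15 + tiny)
    out[selected] = np.sign(u[selected]) * shrunk
    nrm = np.linalg.norm(out)
    if nrm == 0:
        out[selected[0]] = 1.0
        nrm = 1.0
    return out / nrm


def fit_splsda(W, y, keepx, scale: bool = True) -> SplsdaModel:
    """Fit a multilevel sparse PLS-DA model.

    ``W`` is the within-animal deviation matrix (or any samples x features
    matrix), ``y`` the per-sample class labels (e.g. cecum/feces), and
    ``keepx`` the number of features kept per component.
    """
    X, sample_ids, feature_ids = _as_matrix(W)
    keepx = tuple(int(k) for k in np.atleast_1d(keepx))
    labels = np.asarray([str(v) for v in y])
    if labels.size != X.shape[0]:
        raise TableError("labels length does not match number of samples")
    classes = tuple(sorted(set(labels)))
    Y = np.column_stack([(labels == c).astype(float) for c in classes])
    Xc, means, sds = _preprocess(X, feature_ids, scale)
    Yc = Y - Y.mean(axis=0)
    total_ss = float((Xc**2).sum())

    Xh, Yh = Xc.copy(), Yc.copy()
    u_cols, v_cols, xi_cols, omega_cols, var_frac = [], [], [], [], []
    for h, k in enumerate(keepx):
        u, v = _leading_singular_pair(Xh.T @ Yh)
        u = _soft_threshold_exact(u, k)
        xi = Xh @ u
        omega = Yh @ v
        ss_xi = float(xi @ xi)
        if ss_xi > 0:
            c = Xh.T @ xi / ss_xi
            var_frac.append(ss_xi * float(c @ c) / total_ss if total_ss > 0 else 0.0)
            proj = np.outer(xi, xi) / ss_xi
            Xh = Xh - proj @ Xh
            Yh = Yh - proj @ Yh
        else:
            var_frac.append(0.0)
        u_cols.append(u)
        v_cols.append(v)
        xi_cols.append(xi)
        omega_cols.append(omega)

    comp_names = [f"comp{h + 1}" for h in range(len(keepx))]
    return SplsdaModel(
        x_loadings=pd.DataFrame(np.column_stack(u_cols), index=feature_ids, columns=comp_names),
        y_loadings=pd.DataFrame(np.column_stack(v_cols), index=list(classes), columns=comp_names),
        x_variates=pd.DataFrame(np.column_stack(xi_cols), index=sample_ids, columns=comp_names),
        y_variates=pd.DataFrame(np.column_stack(omega_cols), index=sample_ids, columns=comp_names),
        keepx=keepx,
        classes=classes,
        explained_x_variance=np.asarray(var_frac),
        feature_means=means,
        feature_scales=sds,
        scaled=scale,
    )


def feature_contributions(model: SplsdaModel, W, y) -> pd.DataFrame:
    """Signed contribution table of the selected features.

    Each selected feature is assigned to the class with the larger mean
    (processed) abundance; the contribution magnitude is |loading|.
    """
    X, _, feature_ids = _as_matrix(W)
    labels = np.asarray([str(v) for v in y])
    Xp = (X - model.feature_means) / model.feature_scales
    rows = []
    for h in range(model.n_components):
        col = model.x_loadings.iloc[:, h]
        for j, feat in enumerate(feature_ids):
            loading = col.iloc[j]
            if loading == 0.0:
                continue
            class_means = {c: Xp[labels == c, j].mean() for c in model.classes}
            assigned = max(model.classes, key=lambda c: (class_means[c], c))
            rows.append(
                {
                    "component": h + 1,
                    "feature": feat,
                    "loading": float(loading),
                    "magnitude": abs(float(loading)),
                    "class": assigned,
                }
            )
    return pd.DataFrame(rows, columns=["component", "feature", "loading", "magnitude", "class"])


def explained_variance(model: SplsdaModel, W) -> np.ndarray:
    """Per-component explained fraction of the processed X sum of squares.

    Recomputed from ``W`` by replaying the deflation with the fitted
    loadings: var_h = ||xi_h c_h'||_F^2 / ||X_centered||_F^2 with
    c_h = X_h' xi_h / (xi_h' xi_h).
    """
    X, _, feature_ids = _as_matrix(W)
    Xc, _, _ = _preprocess(X, feature_ids, model.scaled)
    total_ss = float((Xc**2).sum())
    fractions = []
    Xh = Xc.copy()
    for h in range(model.n_components):
        u = model.x_loadings.iloc[:, h].to_numpy()
        xi = Xh @ u
        ss_xi = float(xi @ xi)
        if ss_xi == 0 or total_ss == 0:
            fractions.append(0.0)
            continue
        c = Xh.T @ xi / ss_xi
        fractions.append(ss_xi * float(c @ c) / total_ss)
        Xh = Xh - np.outer(xi, xi / ss_xi) @ Xh
    return np.asarray(fractions)
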