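"""Weighted UniFrac, classical PCoA, and the multilevel (paired) PCA.

Weighted UniFrac between samples A and B sums, over every branch i of the
rooted phylogeny, the branch length b_i weighted by the absolute
difference in the fraction of each sample's total abundance found on the
tips descending from that branch:

    d(A, B) = sum_i b_i * | p_A(i) - p_B(i) |

(the raw, unnormalized form; the normalized variant divides by
sum_i b_i (p_A(i) + p_B(i))).  Proportions make the distance invariant to
each sample's sequencing depth and allow real-valued (e.g. CSS) tables.

The multilevel decomposition splits each sample's profile into its
animal's mean (between-animal part) and the deviation from it
(within-animal part); PCA of the within part exposes the cecum-vs-feces
contrast free of animal-to-animal variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix, TreeNode

from cecofec.core_tables import PairedDesign, TableError

__all__ = [
    "OrdinationResult",
    "WithinMatrix",
    "weighted_unifrac",
    "pcoa",
    "within_animal_deviations",
    "paired_pca",
]


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates with eigenvalues / explained-variance fractions.

    ``eigenvalues`` lists every eigenvalue (PCoA may include negative
    ones, which are reported but never embedded); ``proportion_explained``
    covers the embedded axes only.
    """

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    method: str


@dataclass(frozen=True)
class WithinMatrix:
    """Within-animal deviations (samples x OTUs); pair rows sum to zero."""

    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    animal_of_row: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.sample_ids), columns=list(self.otu_ids))


def _as_dataframe(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return table.to_dataframe()


def weighted_unifrac(table, tree: TreeNode, normalize_branch: bool = False) -> DistanceMatrix:
    """Weighted UniFrac distance matrix of every sample pair.

    ``table`` is any samples x OTUs abundance table (integer counts or
    CSS abundances); every OTU must be a tip of ``tree`` and every sample
    must have a positive total.
    """
    df = _as_dataframe(table)
    tip_names = [t.name for t in tree.tips()]
    tip_index = {name: i for i, name in enumerate(tip_names)}
    missing = [o for o in df.columns if o not in tip_index]
    if missing:
        raise TableError(f"OTUs missing from the tree: {missing[:5]}")
    totals = df.to_numpy(dtype=float).sum(axis=1)
    if np.any(totals <= 0):
        bad = [s for s, t in zip(df.index, totals) if t <= 0]
        raise TableError(f"samples with non-positive totals: {bad}")

    # per-tip proportions aligned to tree tip order (absent tips get 0)
    P = np.zeros((df.shape[0], len(tip_names)))
    for otu in df.columns:
        P[:, tip_index[otu]] = df[otu].to_numpy(dtype=float)
    P /= totals[:, None]

    # postorder accumulation of descendant-tip proportion per branch
    branch_lengths = []
    branch_props = []
    node_prop: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            prop = P[:, tip_index[node.name]]
        else:
            prop = np.sum([node_prop.pop(id(c)) for c in node.children], axis=0)
        node_prop[id(node)] = prop
        if node.parent is not None and node.length:
            branch_lengths.append(float(node.length))
            branch_props.append(prop)

    if not branch_lengths:
        data = np.zeros((df.shape[0], df.shape[0]))
        return DistanceMatrix(data, ids=list(df.index))
    b = np.array(branch_lengths)
    M = np.column_stack(branch_props)  # samples x branches
    raw = cdist(M, M, metric="minkowski", p=1, w=b)
    if normalize_branch:
        r = M @ b  # per-sample sum_i b_i p(i)
        denom = r[:, None] + r[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(denom > 0, raw / denom, 0.0)
    np.fill_diagonal(raw, 0.0)
    raw = (raw + raw.T) / 2.0  # enforce exact symmetry for the container
    return DistanceMatrix(raw, ids=list(df.index))


def pcoa(distance_matrix, ids=None, symmetry_tol: float = 1e-8) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower-centers the squared distances, B = -1/2 J (D o D) J, and
    eigendecomposes; coordinates are eigenvectors scaled by sqrt(lambda)
    for positive eigenvalues only.  Negative eigenvalues (non-Euclidean
    distance mass) are reported in ``eigenvalues`` but not embedded, and
    explained-variance fractions are computed over the positive ones.
    """
    if isinstance(distance_matrix, DistanceMatrix):
        D = distance_matrix.data
        ids = list(distance_matrix.ids)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1]:
        raise TableError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=symmetry_tol):
        raise TableError(f"distance matrix asymmetric beyond {symmetry_tol}")
    n = D.shape[0]
    D2 = (D + D.T) / 2.0
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D2**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0.0) * 1e-12 if eigvals.max() > 0 else np.zeros(n, bool)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    proportions = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    coord_df = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{k + 1}" for k in range(coords.shape[1])]
    )
    return OrdinationResult(coord_df, eigvals, proportions, method="pcoa")


def within_animal_deviations(table, design: PairedDesign) -> WithinMatrix:
    """Subtract from each sample its animal's two-sample mean profile.

    Rows are ordered as ``design.sample_ids()`` (cecum block first); the
    two rows of one animal sum to the zero vector by construction.
    """
    df = _as_dataframe(table)
    missing = [s for s in design.sample_ids() if s not in df.index]
    if missing:
        raise TableError(f"design samples missing from table: {missing}")
    X = df.loc[list(design.sample_ids())].to_numpy(dtype=float)
    n = design.n_animals
    # x - (x_C + x_F)/2 = +-(x_C - x_F)/2; computing the half-difference
    # directly makes the pair cancellation exact in floating point
    half_diff = (X[:n] - X[n:]) / 2.0
    W = np.vstack([half_diff, -half_diff])
    return WithinMatrix(
        W,
        design.sample_ids(),
        tuple(df.columns),
        design.animal_ids + design.animal_ids,
    )


def paired_pca(W: WithinMatrix, n_components: int = 2) -> OrdinationResult:
    """PCA of the column-centered within-animal deviation matrix.

    Scores are the samples' coordinates on the leading right singular
    directions; explained-variance fractions are singular values squared
    over the total centered sum of squares.
    """
    X = W.matrix - W.matrix.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating", stacklevel=2
        )
        n_components = rank
    scores = U[:, :n_components] * s[:n_components]
    total_ss = float((s**2).sum())
    proportions = (s[:n_components] ** 2) / total_ss if total_ss > 0 else np.zeros(n_components)
    coord_df = pd.DataFrame(
        scores,
        index=list(W.sample_ids),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return OrdinationResult(coord_df, s**2, proportions, method="paired_pca")
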