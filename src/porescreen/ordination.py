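"""Community dissimilarity and ordination: unweighted UniFrac, PCoA,
one-way PERMANOVA and redundancy analysis (RDA).

All four are implemented directly on top of numpy so that the numerical
definitions are explicit:

* unweighted UniFrac between two samples is the branch length of the
  rooted tree leading to taxa present in exactly one sample, divided by
  the branch length leading to taxa present in either;
* PCoA is the Gower double-centering of -D^2/2 followed by a symmetric
  eigendecomposition, with negative eigenvalues reported as-is;
* PERMANOVA partitions the squared-distance sum into between- and
  within-group components and assesses the pseudo-F by free permutation of
  sample labels;
* RDA projects the column-centered species matrix onto the span of the
  standardized constraints and eigendecomposes the fitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RootedTree",
    "OrdinationResult",
    "PermanovaResult",
    "unweighted_unifrac",
    "unifrac_matrix",
    "pcoa",
    "permanova",
    "rda",
    "factor_fit",
    "read_newick",
    "write_newick",
    "read_distance_tsv",
    "write_distance_tsv",
]


@dataclass
class RootedTree:
    """Rooted phylogeny with non-negative branch lengths and OTU-leaf labels."""

    tree: TreeNode

    def __post_init__(self) -> None:
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if not np.isfinite(node.length) or node.length < 0:
                raise ValueError(f"bad branch length at {node.name!r}")

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def require_leaves(self, otu_ids) -> None:
        missing = set(otu_ids) - set(self.leaf_names)
        if missing:
            raise ValueError(f"OTUs absent from tree: {sorted(missing)[:5]}")


def read_newick(path: str | Path) -> RootedTree:
    return RootedTree(TreeNode.read(str(path)))


def write_newick(tree: RootedTree, path: str | Path) -> None:
    tree.tree.write(str(path))


def _branch_presence(tree: RootedTree, presence: pd.DataFrame):
    """Per-branch presence indicators for a (samples x taxa) boolean frame.

    Returns ``(V, L)``: V is (branches x samples) booleans — whether any
    leaf below the branch is present in the sample — and L the branch
    lengths.  The root's stem is excluded (it has no branch).
    """
    samples = presence.index
    cols = {name: presence[name].to_numpy(bool) for name in presence.columns}
    zeros = np.zeros(len(samples), dtype=bool)
    node_pres: dict[int, np.ndarray] = {}
    V, L = [], []
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            vec = cols.get(node.name, zeros)
        else:
            vec = zeros
            for child in node.children:
                vec = vec | node_pres[id(child)]
        node_pres[id(node)] = vec
        if not node.is_root():
            V.append(vec)
            L.append(node.length)
    return np.array(V), np.array(L, dtype=float)


def unweighted_unifrac(tree: RootedTree, presence_a, presence_b) -> float:
    """Unweighted UniFrac distance between two OTU presence sets."""
    a, b = set(presence_a), set(presence_b)
    if not a and not b:
        raise ValueError("both presence sets are empty")
    tree.require_leaves(a | b)
    taxa = sorted(a | b)
    presence = pd.DataFrame(
        [[t in a for t in taxa], [t in b for t in taxa]],
        index=["a", "b"],
        columns=taxa,
    )
    d = unifrac_matrix(tree, presence)
    return float(d.loc["a", "b"])


def unifrac_matrix(tree: RootedTree, presence: pd.DataFrame) -> pd.DataFrame:
    """All-pairs unweighted UniFrac for a (samples x taxa) presence frame."""
    V, L = _branch_presence(tree, presence)
    Vf = V.astype(float)
    u = L @ Vf  # per-sample total branch length
    W = (Vf * L[:, None]).T @ Vf  # shared branch length per pair
    union = u[:, None] + u[None, :] - W
    uniq = u[:, None] + u[None, :] - 2 * W
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(union > 0, uniq / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # exact symmetry against float jitter
    return pd.DataFrame(D, index=presence.index, columns=presence.index)


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        ids = list(range(D.shape[0]))
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D, ids


@dataclass
class OrdinationResult:
    """Coordinates plus eigenvalue bookkeeping for PCoA/RDA.

    ``eigenvalues`` may contain negative values for a non-Euclidean PCoA
    input; ``proportion_explained`` is computed over the positive part.
    For RDA, ``constrained`` marks the constrained axes and the factor
    arrows live in ``biplot_scores``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    constrained: int | None = None
    biplot_scores: pd.DataFrame | None = None
    r2: float | None = None
    adj_r2: float | None = None


def pcoa(d, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Gower-centers ``-D^2/2`` and eigendecomposes; axes with positive
    eigenvalues are scaled by sqrt(eigenvalue).  Negative eigenvalues are
    reported unchanged (no correction), matching classical metric scaling.
    """
    D, ids = _as_square(d)
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-9 * max(abs(evals[0]), 1.0)).sum())
    if k is None:
        k = n_pos
    elif k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    pos_sum = evals[evals > 0].sum()
    prop = np.where(evals > 0, evals / pos_sum, 0.0) if pos_sum > 0 else evals * 0
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i+1}" for i in range(k)]
        ),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: int | None
    ss_total: float
    ss_within: float


def permanova(
    d, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free label permutation.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within sums the analogous terms
    inside each group (divided by group size); the pseudo-F compares the
    between-group to the within-group mean square.  The p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    D, ids = _as_square(d)
    labels = np.asarray(list(groups))
    if labels.size != D.shape[0]:
        raise ValueError("group labels must match matrix size")
    uniq, inv = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    N = D.shape[0]
    D2 = D**2
    ss_total = D2[np.triu_indices(N, 1)].sum() / N

    onehot = np.eye(a)[inv]  # N x a

    def ss_within(oh: np.ndarray) -> float:
        per_group = np.einsum("ia,ij,ja->a", oh, D2, oh) / 2.0
        return float((per_group / counts).sum())

    ssw = ss_within(onehot)
    ssb = ss_total - ssw
    f_obs = (ssb / (a - 1)) / (ssw / (N - a))

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        ssw_p = ss_within(onehot[perm])
        f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (N - a))
        if f_p >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(ssb / ss_total),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        ss_total=float(ss_total),
        ss_within=float(ssw),
    )


# ---------------------------------------------------------------------------
# redundancy analysis


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = np.zeros_like(X, dtype=float)
    Xs[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep


def rda(y, x, scale: bool = False) -> OrdinationResult:
    """Redundancy analysis: constrained ordination of species on factors.

    ``y`` is the (samples x species) community matrix, column-centered
    internally (and column-standardized when ``scale=True``); ``x`` the
    (samples x constraints) factor matrix, standardized internally.  The
    fitted values of the multivariate regression of Y on X are
    eigendecomposed; R^2 is the fitted share of the total variance and the
    adjusted R^2 uses the Ezekiel formula with m = number of (independent)
    constraints.
    """
    Y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[0] != Y.shape[0]:
        X = X.T
    if X.shape[0] != Y.shape[0]:
        raise ValueError("y and x row counts differ")
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    if scale:
        sd = Yc.std(axis=0, ddof=1)
        Yc = np.divide(Yc, sd, out=np.zeros_like(Yc), where=sd > 0)
    Xs, keep = _standardize_columns(X)
    if not keep.all():
        warnings.warn("dropping constant constraint columns", stacklevel=2)
        Xs = Xs[:, keep]
    rank = np.linalg.matrix_rank(Xs) if Xs.size else 0
    if rank == 0:
        raise ValueError("no usable constraints")
    if rank < Xs.shape[1]:
        warnings.warn("collinear constraints: using pseudo-inverse fit", stacklevel=2)
    B = np.linalg.pinv(Xs) @ Yc
    Yhat = Xs @ B
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    lam = s**2 / (n - 1)
    n_axes = int((s > 1e-9 * max(s[0], 1.0)).sum()) if s.size else 0
    ss_total = (Yc**2).sum()
    ss_fit = (s**2).sum()
    r2 = float(ss_fit / ss_total) if ss_total > 0 else 0.0
    m = rank
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1) if n - m - 1 > 0 else np.nan
    coords = U[:, :n_axes] * s[:n_axes]
    names = [f"RDA{i+1}" for i in range(n_axes)]
    coords_df = pd.DataFrame(coords, columns=names)
    # factor arrows: correlations of constraints with the constrained axes
    biplot = np.zeros((Xs.shape[1], n_axes))
    for j in range(Xs.shape[1]):
        for i in range(n_axes):
            cs = np.std(coords[:, i])
            biplot[j, i] = (
                np.corrcoef(Xs[:, j], coords[:, i])[0, 1] if cs > 0 else 0.0
            )
    lam_sum = lam[:n_axes].sum()
    prop = lam[:n_axes] / lam_sum if lam_sum > 0 else lam[:n_axes] * 0
    return OrdinationResult(
        coordinates=coords_df,
        eigenvalues=lam[:n_axes],
        proportion_explained=prop,
        constrained=n_axes,
        biplot_scores=pd.DataFrame(biplot, columns=names),
        r2=r2,
        adj_r2=float(adj),
    )


@dataclass(frozen=True)
class FactorFit:
    """Marginal single-constraint RDA summary for one factor (Table-2 shape).

    ``rda1``/``rda2`` are the factor's arrow coordinates (correlation with
    the joint model's first two constrained axes) when a joint model is
    supplied, otherwise with its own marginal axes.  Two adjusted R^2
    variants are carried: the per-fit Ezekiel value and a global-ratio
    scaling ``r2 * (model adjusted R^2 / model R^2)``.
    """

    factor: str
    rda1: float
    rda2: float
    r2: float
    adj_r2_ezekiel: float
    adj_r2_global_ratio: float | None
    p_value: float
    n_permutations: int


def factor_fit(
    y,
    factor_values,
    *,
    name: str = "factor",
    n_perm: int = 999,
    seed: int | None = None,
    joint_axes: pd.DataFrame | None = None,
    model_adj_ratio: float | None = None,
) -> FactorFit:
    """Marginal RDA fit of one environmental factor.

    The p-value permutes the factor vector and compares marginal R^2
    (one-sided).  ``model_adj_ratio`` is the joint model's adjusted-R^2 /
    R^2 ratio used for the global-ratio adjusted variant.
    """
    x = np.asarray(factor_values, dtype=float)
    if np.unique(x[np.isfinite(x)]).size < 2:
        return FactorFit(name, np.nan, np.nan, np.nan, np.nan, None, np.nan, 0)
    res = rda(y, x[:, None])
    if joint_axes is not None and joint_axes.shape[1] >= 1:
        ax = joint_axes.to_numpy(dtype=float)
        r1 = float(np.corrcoef(x, ax[:, 0])[0, 1])
        r2ax = float(np.corrcoef(x, ax[:, 1])[0, 1]) if ax.shape[1] > 1 else np.nan
    else:
        r1 = float(res.biplot_scores.iloc[0, 0]) if res.biplot_scores is not None else np.nan
        r2ax = np.nan
    # single-constraint R^2 has a closed form: ||x_c^T Y_c||^2 / (||x_c||^2 SS_tot)
    Y = np.asarray(y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    ss_total = (Yc**2).sum()

    def _marginal_r2(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        denom = (xc**2).sum()
        if denom == 0 or ss_total == 0:
            return 0.0
        return float(((xc @ Yc) ** 2).sum() / denom / ss_total)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        if _marginal_r2(rng.permutation(x)) >= res.r2 - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    global_adj = res.r2 * model_adj_ratio if model_adj_ratio is not None else None
    return FactorFit(
        factor=name,
        rda1=r1,
        rda2=r2ax,
        r2=res.r2,
        adj_r2_ezekiel=res.adj_r2,
        adj_r2_global_ratio=global_adj,
        p_value=float(p),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# distance-matrix I/O


def read_distance_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    _as_square(df)
    return df


def write_distance_tsv(d: pd.DataFrame, path: str | Path) -> None:
    d.rename_axis("sample_id").to_csv(path, sep="\t")
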