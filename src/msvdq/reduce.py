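"""Dimensionality reduction for both workflow branches.

PCA (on the imputed numeric matrix) and MCA (correspondence analysis of the
indicator expansion of the categorical missingness matrix) both reduce to a
small number of axes, and both expose a per-variable *contribution* score —
the explained-variance-weighted squared loading (PCA) or the aggregated
category contribution (MCA) — used to rank the most influential questions.

Both decompositions carry a deterministic sign convention (the largest-
magnitude loading / category coordinate of each axis is positive) so that
repeated runs are byte-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ScopeError
from .preprocess import EncodedMatrix


@dataclass
class ReducedScores:
    """Low-dimensional row scores plus the apparatus to interpret them.

    ``loadings`` is the p x k loading matrix for PCA or the category
    principal-coordinate table for MCA.  ``explained`` holds the fraction of
    total variance (PCA) / total inertia (MCA) per retained axis.
    ``contributions`` is the per-variable importance used by
    :func:`top_contributors`.
    """

    scores: np.ndarray
    loadings: pd.DataFrame
    explained: np.ndarray
    eigenvalues: np.ndarray
    contributions: pd.Series
    site: np.ndarray
    feature_names: list[str]
    method: str
    dropped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def restrict_rows(self, idx: np.ndarray) -> "ReducedScores":
        return ReducedScores(
            scores=self.scores[idx],
            loadings=self.loadings,
            explained=self.explained,
            eigenvalues=self.eigenvalues,
            contributions=self.contributions,
            site=self.site[idx],
            feature_names=self.feature_names,
            method=self.method,
            dropped=list(self.dropped),
        )


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Flip each axis so its largest-magnitude loading is positive (in place)."""
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1.0
            scores[:, a] *= -1.0


def pca_reduce(
    m: EncodedMatrix, k: int = 3, standardize: bool = True
) -> ReducedScores:
    """Principal component analysis of a complete encoded matrix.

    Columns are centred (and, by default, scaled to unit sample variance)
    before the singular value decomposition; zero-variance columns are
    dropped with a warning since scaling is undefined for them.
    """
    if m.mask.any():
        raise ValueError("pca_reduce requires a complete matrix (impute first)")
    X = m.values.astype(float)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need n > k rows (n={n}, k={k})")
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = [c for c, ok in zip(m.columns, keep) if not ok]
    if dropped:
        warnings.warn(f"dropping zero-variance column(s): {dropped}")
    X = X[:, keep]
    names = [c for c, ok in zip(m.columns, keep) if ok]
    if X.shape[1] == 0:
        raise ScopeError("all columns have zero variance")
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / X.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k_eff = min(k, len(S))
    eigenvalues = S**2 / (n - 1)
    explained = (eigenvalues / eigenvalues.sum())[:k_eff]
    loadings = Vt[:k_eff].T.copy()
    scores = (U[:, :k_eff] * S[:k_eff]).copy()
    _fix_signs(loadings, scores)
    contrib = pd.Series(
        (loadings**2 @ explained), index=names, name="contribution"
    )
    return ReducedScores(
        scores=scores,
        loadings=pd.DataFrame(
            loadings, index=names, columns=[f"axis{a+1}" for a in range(k_eff)]
        ),
        explained=explained,
        eigenvalues=eigenvalues[:k_eff],
        contributions=contrib,
        site=m.site.copy(),
        feature_names=names,
        method="pca",
        dropped=dropped,
    )


def mca_reduce(
    cat: pd.DataFrame, k: int = 3, site: np.ndarray | None = None
) -> ReducedScores:
    """Multiple correspondence analysis via CA of the indicator matrix.

    Build the complete disjunctive matrix Z, form the correspondence matrix
    P = Z / sum(Z), take the standardized residuals
    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}, and decompose S by SVD.  Row
    scores are the principal coordinates on the top-k axes; the explained
    fractions are the squared singular values over their total inertia.
    Constant columns (a single observed level) carry no information and are
    dropped with a warning.
    """
    if cat.isna().any().any():
        raise ValueError("mca_reduce requires a complete categorical table")
    nlevels = cat.nunique()
    dropped = [c for c in cat.columns if nlevels[c] < 2]
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}")
        cat = cat.drop(columns=dropped)
    if cat.shape[1] == 0:
        raise ScopeError("all columns constant; MCA undefined")
    n = len(cat)
    var_of_col: list[str] = []
    blocks = []
    cat_names: list[str] = []
    for col in cat.columns:
        dummies = pd.get_dummies(cat[col], prefix=col, prefix_sep="=")
        blocks.append(dummies.to_numpy(dtype=float))
        cat_names.extend(dummies.columns)
        var_of_col.extend([col] * dummies.shape[1])
    Z = np.hstack(blocks)
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # non-trivial axes: at most (total categories - number of variables)
    max_axes = max(Z.shape[1] - cat.shape[1], 1)
    k_eff = min(k, max_axes, len(sv))
    inertia = sv**2
    total_inertia = inertia.sum()
    if total_inertia > 0:
        explained = (inertia / total_inertia)[:k_eff]
    else:
        explained = np.zeros(k_eff)
    row_coords = (U[:, :k_eff] * sv[:k_eff]) / np.sqrt(r)[:, None]
    col_coords = (Vt[:k_eff].T * sv[:k_eff]) / np.sqrt(c)[:, None]
    _fix_signs(col_coords, row_coords)
    # category contribution to axis a: c_j * G_ja^2 / sigma_a^2 (sums to 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ctr = c[:, None] * col_coords**2 / inertia[:k_eff]
    ctr = np.nan_to_num(ctr)
    var_ctr = (
        pd.DataFrame(ctr, index=cat_names)
        .groupby(pd.Series(var_of_col, index=cat_names), sort=False)
        .sum()
        .reindex(list(cat.columns))
    )
    contrib = pd.Series(
        var_ctr.to_numpy() @ explained, index=list(cat.columns), name="contribution"
    )
    return ReducedScores(
        scores=row_coords,
        loadings=pd.DataFrame(
            col_coords, index=cat_names, columns=[f"axis{a+1}" for a in range(k_eff)]
        ),
        explained=explained,
        eigenvalues=inertia[:k_eff],
        contributions=contrib,
        site=np.asarray(site) if site is not None else np.zeros(n, dtype=object),
        feature_names=list(cat.columns),
        method="mca",
        dropped=dropped,
    )


def top_contributors(r: ReducedScores, k_vars: int = 20) -> pd.Series:
    """The k_vars variables with the highest contribution scores.

    Descending order; ties keep the original variable order (stable sort).
    Asking for more variables than exist returns them all with a warning.
    """
    if r.k < 1:
        raise ValueError("need at least one retained axis")
    contrib = r.contributions
    if k_vars > len(contrib):
        warnings.warn(
            f"k_vars={k_vars} exceeds {len(contrib)} variables; returning all"
        )
        k_vars = len(contrib)
    order = np.argsort(-contrib.to_numpy(), kind="stable")
    return contrib.iloc[order[:k_vars]]
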