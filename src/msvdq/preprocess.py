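"""Variable selection, numeric encoding and chained-equations imputation.

The values branch of the workflow analyses only categorical, ordinal and
continuous questions; free-text and multichoice items are excluded.
Categorical/ordinal answers are encoded as the 0-based index of their label
in the declared category order; blanks become a missing mask.  Missing
entries are then filled by chained-equations (MICE-style) imputation: mean
initialisation, then column-by-column ridge regressions on all other
features until the imputed values stabilise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from ._errors import DatasetError, ImputationError
from .codebook import Codebook, MultiSourceDataset


@dataclass
class EncodedMatrix:
    """Numeric n x p matrix with an explicit missingness mask.

    Masked cells hold NaN and are never used in computation.  ``encoders``
    maps each categorical/ordinal column to its ordered category labels
    (empty tuple for continuous columns).
    """

    values: np.ndarray
    mask: np.ndarray
    columns: list[str]
    encoders: dict[str, tuple[str, ...]]
    site: np.ndarray
    sections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, columns: list[str]) -> "EncodedMatrix":
        idx = [self.columns.index(c) for c in columns]
        return EncodedMatrix(
            values=self.values[:, idx].copy(),
            mask=self.mask[:, idx].copy(),
            columns=list(columns),
            encoders={c: self.encoders[c] for c in columns},
            site=self.site.copy(),
            sections={c: self.sections[c] for c in columns if c in self.sections},
        )


def select_analyzable(codebook: Codebook) -> list[str]:
    """Ids of categorical/ordinal/continuous variables, codebook order."""
    return [v.id for v in codebook if v.is_analyzable]


def encode(ds: MultiSourceDataset, codebook: Codebook) -> EncodedMatrix:
    """Numeric encoding of the analyzable columns present in the dataset.

    Categorical/ordinal labels map to their index in the declared order;
    continuous cells are parsed as floats (an unparseable cell is an error
    with its coordinates); blanks set the mask.
    """
    ids = [c for c in select_analyzable(codebook) if c in ds.data.columns]
    n = ds.n
    values = np.full((n, len(ids)), np.nan)
    mask = np.zeros((n, len(ids)), dtype=bool)
    encoders: dict[str, tuple[str, ...]] = {}
    sections: dict[str, str] = {}
    for j, col in enumerate(ids):
        spec = codebook[col]
        encoders[col] = spec.categories
        sections[col] = spec.section
        cells = ds.data[col]
        missing = cells.isna().to_numpy()
        mask[:, j] = missing
        if spec.vtype == "continuous":
            parsed = pd.to_numeric(cells, errors="coerce")
            bad = parsed.isna().to_numpy() & ~missing
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise DatasetError(
                    f"unparseable numeric {cells.iloc[row]!r} at (row {row}, "
                    f"column {col!r})"
                )
            values[:, j] = parsed.to_numpy(dtype=float)
        else:
            code_of = {label: k for k, label in enumerate(spec.categories)}
            codes = cells.map(code_of)
            values[~missing, j] = codes.to_numpy(dtype=float)[~missing]
    return EncodedMatrix(
        values=values,
        mask=mask,
        columns=ids,
        encoders=encoders,
        site=ds.site.to_numpy(),
        sections=sections,
    )


def impute_chained(
    m: EncodedMatrix,
    max_iter: int = 10,
    tol: float = 1e-3,
    ridge_lambda: float = 1e-3,
    seed: int = 0,
) -> tuple[EncodedMatrix, list[float]]:
    """Chained-equations imputation with fixed-penalty ridge regressions.

    Missing cells are initialised with column means, then each incomplete
    column (visited in ascending missing count, ties by column order) is
    regressed on all other columns — current imputations filled in — with an
    L2-penalised linear fit on the rows where it is observed; its missing
    cells are overwritten with the predictions.  Sweeps stop when the
    largest absolute change of any imputed cell falls below ``tol`` times
    that column's observed SD, or after ``max_iter`` sweeps.  Imputation is
    pooled over all sites.  Categorical/ordinal columns are finally rounded
    to the nearest valid code.

    Returns the completed matrix (mask all False) and the per-sweep
    convergence trace (max relative change).  The algorithm is
    deterministic; ``seed`` is accepted for interface stability and recorded
    nowhere else.
    """
    del seed
    X = m.values.copy()
    mask = m.mask.copy()
    n, p = X.shape
    if n < 2:
        raise ImputationError("need at least 2 rows to impute")
    fully_missing = [m.columns[j] for j in range(p) if mask[:, j].all()]
    if fully_missing:
        raise ImputationError(f"fully missing column(s): {fully_missing}")

    col_means = np.array(
        [X[~mask[:, j], j].mean() for j in range(p)]
    )
    col_sds = np.array(
        [X[~mask[:, j], j].std(ddof=0) for j in range(p)]
    )
    for j in range(p):
        X[mask[:, j], j] = col_means[j]

    incomplete = [j for j in range(p) if mask[:, j].any()]
    # ascending missing count, ties broken by column order (stable sort)
    incomplete.sort(key=lambda j: int(mask[:, j].sum()))
    trace: list[float] = []
    if not incomplete:
        return _finalize(m, X), trace

    for _ in range(max_iter):
        worst = 0.0
        for j in incomplete:
            obs = ~mask[:, j]
            others = [k for k in range(p) if k != j]
            design = X[:, others]
            y = X[:, j]
            if ridge_lambda == 0.0:
                beta, _, rank, _ = np.linalg.lstsq(
                    np.column_stack([np.ones(int(obs.sum())), design[obs]]),
                    y[obs],
                    rcond=None,
                )
                if rank < len(others) + 1:
                    raise ImputationError(
                        f"singular design while imputing {m.columns[j]!r}; "
                        "use ridge_lambda > 0"
                    )
                pred = np.column_stack([np.ones(n), design]) @ beta
            else:
                model = Ridge(alpha=ridge_lambda)
                model.fit(design[obs], y[obs])
                pred = model.predict(design[mask[:, j]])
            old = X[mask[:, j], j]
            new = pred if ridge_lambda != 0.0 else pred[mask[:, j]]
            scale = col_sds[j] if col_sds[j] > 0 else 1.0
            change = float(np.max(np.abs(new - old))) / scale if len(old) else 0.0
            worst = max(worst, change)
            X[mask[:, j], j] = new
        trace.append(worst)
        if worst < tol:
            break
    return _finalize(m, X), trace


def _finalize(m: EncodedMatrix, X: np.ndarray) -> EncodedMatrix:
    """Round imputed categorical/ordinal cells to valid codes; clear mask."""
    X = X.copy()
    for j, col in enumerate(m.columns):
        cats = m.encoders.get(col, ())
        if cats:
            imputed = m.mask[:, j]
            X[imputed, j] = np.clip(np.rint(X[imputed, j]), 0, len(cats) - 1)
    if not np.array_equal(X[~m.mask], m.values[~m.mask]):
        # observed cells must never be altered by imputation
        raise ImputationError("internal error: observed cells changed")
    return EncodedMatrix(
        values=X,
        mask=np.zeros_like(m.mask),
        columns=list(m.columns),
        encoders=dict(m.encoders),
        site=m.site.copy(),
        sections=dict(m.sections),
    )


def mean_impute(m: EncodedMatrix) -> EncodedMatrix:
    """Baseline: fill every missing cell with its column's observed mean."""
    X = m.values.copy()
    for j in range(m.p):
        obs = ~m.mask[:, j]
        if not obs.any():
            raise ImputationError(f"fully missing column(s): [{m.columns[j]!r}]")
        X[m.mask[:, j], j] = X[obs, j].mean()
    return _finalize(m, X)
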