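"""Branching-aware classification of blank cells.

Every cell of the participant table is assigned one of three codes:

* ``0`` ordinary missing — a blank answer to a question that applied,
* ``1`` dependent (not-applicable) missing — a blank caused by skip logic:
  the parent question's answer put the child out of scope,
* ``2`` non-missing.

The rule set is carried entirely by the codebook's branch entries.  When
the parent of a blank child is itself blank, the child's applicability is
resolved through the parent's own code: a not-applicable parent propagates
not-applicability down the chain (``cascade="propagate"``, the default); a
conservative mode (``cascade="ordinary"``) codes every blank-parent child
as ordinary, which never understates data-collection faults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import CodebookError
from .codebook import Codebook, MultiSourceDataset, round_half_away

ORDINARY, NOT_APPLICABLE, OBSERVED = 0, 1, 2
CODE_LABELS = {ORDINARY: "ordinary", NOT_APPLICABLE: "not_applicable", OBSERVED: "observed"}
_MAX_CHAIN_DEPTH = 10


@dataclass
class MissingCategoryMatrix:
    """n x p integer matrix of codes {0, 1, 2} with row sites and sections."""

    codes: pd.DataFrame
    site: pd.Series
    sections: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.codes.to_numpy()
        if not np.isin(vals, (ORDINARY, NOT_APPLICABLE, OBSERVED)).all():
            raise ValueError("codes must be 0, 1 or 2")

    @property
    def n_cells(self) -> int:
        return int(self.codes.size)

    def subset(self, columns: list[str]) -> "MissingCategoryMatrix":
        return MissingCategoryMatrix(
            codes=self.codes[columns].copy(),
            site=self.site,
            sections={c: self.sections[c] for c in columns},
        )


def _chain_depth(codebook: Codebook, var_id: str) -> int:
    depth = 0
    cur = codebook[var_id]
    while cur.branch_rule is not None:
        depth += 1
        if depth > _MAX_CHAIN_DEPTH:
            raise CodebookError(f"branch chain deeper than {_MAX_CHAIN_DEPTH} at {var_id!r}")
        cur = codebook[cur.branch_rule.parent_id]
    return depth


def categorize(
    ds: MultiSourceDataset, codebook: Codebook, cascade: str = "propagate"
) -> MissingCategoryMatrix:
    """Assign every cell its missingness code.

    Non-blank cells are 2.  A blank cell in a branch-gated column is 1 when
    the parent's observed value lies outside the activating set, 0 when the
    parent's observed value activated the child.  Blank parents are
    resolved per ``cascade`` (see module docstring).  Deterministic and
    independent of row order.
    """
    if cascade not in ("propagate", "ordinary"):
        raise ValueError("cascade must be 'propagate' or 'ordinary'")
    cols = list(ds.data.columns)
    codes = pd.DataFrame(ORDINARY, index=ds.data.index, columns=cols, dtype=np.int8)
    codes[ds.data.notna()] = OBSERVED
    # parents before children: resolve in ascending chain depth
    for col in sorted(cols, key=lambda c: _chain_depth(codebook, c)):
        rule = codebook[col].branch_rule
        if rule is None:
            continue
        blank = ds.data[col].isna().to_numpy()
        if not blank.any():
            continue
        parent_vals = ds.data[rule.parent_id] if rule.parent_id in ds.data else None
        if parent_vals is None:
            continue  # parent column absent: all blanks stay ordinary
        parent_obs = parent_vals.notna().to_numpy()
        inactive = parent_obs & ~parent_vals.isin(list(rule.activating_values)).to_numpy()
        out = np.flatnonzero(blank & inactive)
        codes.iloc[out, codes.columns.get_loc(col)] = NOT_APPLICABLE
        if cascade == "propagate":
            parent_na = (codes[rule.parent_id].to_numpy() == NOT_APPLICABLE) & ~parent_obs
            out2 = np.flatnonzero(blank & parent_na)
            codes.iloc[out2, codes.columns.get_loc(col)] = NOT_APPLICABLE
    sections = {c: codebook[c].section for c in cols}
    return MissingCategoryMatrix(codes=codes, site=ds.site, sections=sections)


@dataclass
class CompletenessSummary:
    """Counts and percentage shares of each code at several granularities."""

    total_cells: int
    counts: dict[str, int]
    percents: dict[str, float]  # 1-decimal shares, half away from zero
    by_site: pd.DataFrame
    by_section: pd.DataFrame
    by_site_section: pd.DataFrame
    by_variable: pd.DataFrame
    complete_percent_whole: int = field(init=False)

    def __post_init__(self) -> None:
        # whole-percent display style for the overall complete share
        self.complete_percent_whole = int(
            round_half_away(100.0 * self.counts["observed"] / self.total_cells, 0)
        )


def _tabulate(codes: np.ndarray) -> dict[str, int]:
    return {
        label: int((codes == code).sum()) for code, label in CODE_LABELS.items()
    }


def _share_row(counts: dict[str, int]) -> dict[str, float | int]:
    total = sum(counts.values())
    row: dict[str, float | int] = {f"{k}_n": v for k, v in counts.items()}
    for k, v in counts.items():
        row[f"{k}_pct"] = round_half_away(100.0 * v / total, 1) if total else np.nan
    return row


def completeness_summary(m: MissingCategoryMatrix) -> CompletenessSummary:
    """Overall, per-site, per-section, per-site-x-section and per-variable
    counts of the three codes, with 1-decimal percentage shares."""
    if m.n_cells == 0:
        raise ValueError("empty category matrix")
    vals = m.codes.to_numpy()
    counts = _tabulate(vals)
    percents = {
        k: round_half_away(100.0 * v / m.n_cells, 1) for k, v in counts.items()
    }

    site_arr = m.site.to_numpy()
    site_labels = list(dict.fromkeys(site_arr))
    by_site = pd.DataFrame(
        [_share_row(_tabulate(vals[site_arr == s])) for s in site_labels],
        index=site_labels,
    )

    section_of = np.array([m.sections[c] for c in m.codes.columns])
    section_labels = list(dict.fromkeys(section_of))
    by_section = pd.DataFrame(
        [_share_row(_tabulate(vals[:, section_of == sec])) for sec in section_labels],
        index=section_labels,
    )

    rows, idx = [], []
    for s in site_labels:
        for sec in section_labels:
            block = vals[np.ix_(site_arr == s, section_of == sec)]
            rows.append(_share_row(_tabulate(block)))
            idx.append((s, sec))
    by_site_section = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(idx, names=["site", "section"])
    )

    by_variable = pd.DataFrame(
        [_share_row(_tabulate(vals[:, j])) for j in range(vals.shape[1])],
        index=list(m.codes.columns),
    )
    return CompletenessSummary(
        total_cells=m.n_cells,
        counts=counts,
        percents=percents,
        by_site=by_site,
        by_section=by_section,
        by_site_section=by_site_section,
        by_variable=by_variable,
    )


def to_categorical_table(
    m: MissingCategoryMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Three-level categorical table for MCA plus the constant-column flags.

    Columns with a single observed level (typically all-observed sections)
    carry no missingness information and are listed for MCA's drop rule.
    """
    table = m.codes.replace(CODE_LABELS).astype(object)
    constant = [c for c in table.columns if table[c].nunique() < 2]
    return table, constant
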