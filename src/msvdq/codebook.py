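"""Questionnaire codebook and multi-site dataset model.

A *codebook* declares, for every question of a survey, its section, its
measurement type (categorical / ordinal / continuous / text / multichoice),
the ordered category labels where applicable, and an optional *branch rule*:
the question only applies when a parent question took one of a set of
activating values (skip logic).  A *multi-source dataset* is a flat table of
participant responses, one row per participant, labelled by collection site,
with blanks preserved as missing markers.

The codebook is the single carrier of questionnaire semantics: downstream
stages (encoding, imputation, missingness categorisation) never need a
second rules file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import CodebookError, DatasetError

VTYPES = ("categorical", "ordinal", "continuous", "text", "multichoice")
#: variable types that enter the numeric analysis branch
ANALYZABLE_VTYPES = ("categorical", "ordinal", "continuous")

DEFAULT_NA_VALUES = ("", "NA")
DEFAULT_SITE_COL = "site"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percentage tables)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class BranchRule:
    """Skip-logic rule: the child question applies only when the parent's
    answer is one of ``activating_values``."""

    parent_id: str
    activating_values: frozenset[str]

    def __post_init__(self) -> None:
        if not self.activating_values:
            raise CodebookError(
                f"branch rule on parent {self.parent_id!r} has no activating values"
            )
        object.__setattr__(self, "activating_values", frozenset(self.activating_values))


@dataclass(frozen=True)
class VariableSpec:
    """One question: identifier, section, type, ordered categories, branch rule."""

    id: str
    section: str
    vtype: str
    categories: tuple[str, ...] = ()
    branch_rule: BranchRule | None = None

    def __post_init__(self) -> None:
        if self.vtype not in VTYPES:
            raise CodebookError(f"variable {self.id!r}: unknown vtype {self.vtype!r}")
        object.__setattr__(self, "categories", tuple(self.categories))
        if self.vtype in ("categorical", "ordinal"):
            if len(set(self.categories)) < 2:
                raise CodebookError(
                    f"variable {self.id!r}: {self.vtype} needs >=2 distinct categories"
                )
            if len(set(self.categories)) != len(self.categories):
                raise CodebookError(f"variable {self.id!r}: duplicate category labels")
        elif self.categories:
            raise CodebookError(
                f"variable {self.id!r}: {self.vtype} must not declare categories"
            )

    @property
    def is_analyzable(self) -> bool:
        return self.vtype in ANALYZABLE_VTYPES


class Codebook:
    """Validated, ordered collection of :class:`VariableSpec`.

    Enforces: unique ids, branch parents exist and are categorical/ordinal,
    activating values are declared parent categories, no self-reference and
    no cyclic parent chains.
    """

    def __init__(self, variables: Iterable[VariableSpec]):
        self.variables: list[VariableSpec] = list(variables)
        self._by_id: dict[str, VariableSpec] = {}
        for v in self.variables:
            if v.id in self._by_id:
                raise CodebookError(f"duplicate variable id {v.id!r}")
            self._by_id[v.id] = v
        for v in self.variables:
            rule = v.branch_rule
            if rule is None:
                continue
            if rule.parent_id == v.id:
                raise CodebookError(f"variable {v.id!r}: branch rule references itself")
            parent = self._by_id.get(rule.parent_id)
            if parent is None:
                raise CodebookError(
                    f"variable {v.id!r}: branch parent {rule.parent_id!r} not in codebook"
                )
            if parent.vtype not in ("categorical", "ordinal"):
                raise CodebookError(
                    f"variable {v.id!r}: branch parent {rule.parent_id!r} is "
                    f"{parent.vtype}, must be categorical/ordinal"
                )
            unknown = rule.activating_values - set(parent.categories)
            if unknown:
                raise CodebookError(
                    f"variable {v.id!r}: activating values {sorted(unknown)} are not "
                    f"categories of parent {rule.parent_id!r}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for v in self.variables:
            seen = {v.id}
            cur = v
            while cur.branch_rule is not None:
                nxt = self._by_id[cur.branch_rule.parent_id]
                if nxt.id in seen:
                    raise CodebookError(
                        f"cyclic branch chain involving {nxt.id!r}"
                    )
                seen.add(nxt.id)
                cur = nxt

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, var_id: str) -> bool:
        return var_id in self._by_id

    def __getitem__(self, var_id: str) -> VariableSpec:
        try:
            return self._by_id[var_id]
        except KeyError:
            raise KeyError(f"variable {var_id!r} not in codebook") from None

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variables]

    @property
    def sections(self) -> list[str]:
        """Section names in first-appearance order."""
        out: list[str] = []
        for v in self.variables:
            if v.section not in out:
                out.append(v.section)
        return out

    def section_ids(self, section: str) -> list[str]:
        return [v.id for v in self.variables if v.section == section]

    def to_dict(self) -> dict:
        out = []
        for v in self.variables:
            d: dict = {"id": v.id, "section": v.section, "vtype": v.vtype}
            if v.categories:
                d["categories"] = list(v.categories)
            if v.branch_rule is not None:
                d["branch"] = {
                    "parent": v.branch_rule.parent_id,
                    "values": sorted(v.branch_rule.activating_values),
                }
            out.append(d)
        return {"variables": out}

    @classmethod
    def from_dict(cls, data: Mapping) -> "Codebook":
        try:
            raw = data["variables"]
        except (KeyError, TypeError):
            raise CodebookError("codebook must be a mapping with a 'variables' list")
        specs = []
        for entry in raw:
            branch = None
            if entry.get("branch") is not None:
                b = entry["branch"]
                branch = BranchRule(
                    parent_id=b["parent"], activating_values=frozenset(b["values"])
                )
            specs.append(
                VariableSpec(
                    id=str(entry["id"]),
                    section=str(entry.get("section", "default")),
                    vtype=str(entry["vtype"]),
                    categories=tuple(str(c) for c in entry.get("categories", ())),
                    branch_rule=branch,
                )
            )
        return cls(specs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=1)
        if path.suffix in (".yaml", ".yml"):
            text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        path.write_text(text)


def load_codebook(path: str | Path) -> Codebook:
    """Read a codebook from JSON or YAML.

    Schema: ``{variables: [{id, section, vtype, categories?, branch?: {parent,
    values}}]}``.  All structural invariants are enforced on load.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return Codebook.from_dict(data)


@dataclass
class MultiSourceDataset:
    """Site-labelled participant table with blanks kept as ``NaN``.

    ``data`` holds raw string cells (object dtype); missing cells are NaN.
    The site column is stored separately in ``site``.
    """

    data: pd.DataFrame
    site: pd.Series
    codebook: Codebook = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise DatasetError("no records")
        unknown = [c for c in self.data.columns if c not in self.codebook]
        if unknown:
            raise DatasetError(f"columns not in codebook: {unknown}")
        for col in self.data.columns:
            spec = self.codebook[col]
            if spec.vtype in ("categorical", "ordinal"):
                cells = self.data[col]
                bad = cells.notna() & ~cells.isin(spec.categories)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise DatasetError(
                        f"invalid category {cells.iloc[row]!r} at (row {row}, "
                        f"column {col!r}); declared: {list(spec.categories)}"
                    )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        """Site labels in first-appearance order."""
        out: list[str] = []
        for s in self.site:
            if s not in out:
                out.append(s)
        return out

    def site_counts(self) -> pd.Series:
        return self.site.value_counts().reindex(self.sites)


def load_dataset(
    path: str | Path,
    codebook: Codebook,
    site_col: str = DEFAULT_SITE_COL,
    na_values: Sequence[str] = DEFAULT_NA_VALUES,
) -> MultiSourceDataset:
    """Read a participant CSV (header row, one row per participant).

    Cells equal to any sentinel in ``na_values`` (default ``""`` and ``"NA"``)
    become missing; everything else is kept verbatim as a string.  Row order
    is preserved.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DatasetError("no records") from None
    if len(frame) == 0:
        raise DatasetError("no records")
    if site_col not in frame.columns:
        raise DatasetError(f"site column {site_col!r} not found")
    site = frame[site_col].copy()
    data = frame.drop(columns=[site_col])
    data = data.where(~data.isin(list(na_values)), other=np.nan)
    return MultiSourceDataset(data=data, site=site, codebook=codebook)


def write_dataset(
    ds: MultiSourceDataset, path: str | Path, site_col: str = DEFAULT_SITE_COL
) -> None:
    """Write back to CSV, blanks as empty cells (round-trips with
    :func:`load_dataset` under the default sentinels)."""
    out = ds.data.copy()
    out.insert(0, site_col, ds.site.to_numpy())
    out.to_csv(path, index=False, na_rep="")


def summarize_demographics(
    ds: MultiSourceDataset, age_var: str, sex_var: str
) -> pd.DataFrame:
    """Per-site sample size, percentage share, age mean/SD and sex breakdown.

    Shares are ``100*n_site/n_total`` rounded to one decimal, half away from
    zero; the age SD uses the sample (n-1) denominator.  A site with no
    observed ages gets NaN age fields rather than an error.
    """
    if ds.codebook[age_var].vtype != "continuous":
        raise DatasetError(f"age variable {age_var!r} must be continuous")
    if ds.codebook[sex_var].vtype not in ("categorical", "ordinal"):
        raise DatasetError(f"sex variable {sex_var!r} must be categorical")
    total = ds.n
    sex_levels = ds.codebook[sex_var].categories
    rows = []
    for label in ds.sites:
        mask = (ds.site == label).to_numpy()
        n_site = int(mask.sum())
        ages = pd.to_numeric(ds.data.loc[mask, age_var], errors="coerce").dropna()
        row: dict = {
            "site": label,
            "n": n_site,
            "share_pct": round_half_away(100.0 * n_site / total, 1),
            "age_mean": float(ages.mean()) if len(ages) else np.nan,
            "age_sd": float(ages.std(ddof=1)) if len(ages) > 1 else np.nan,
        }
        sex = ds.data.loc[mask, sex_var]
        for level in sex_levels:
            k = int((sex == level).sum())
            row[f"{level}_n"] = k
            row[f"{level}_pct"] = round_half_away(100.0 * k / n_site, 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")
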