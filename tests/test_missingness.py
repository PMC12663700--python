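import numpy as np
import pandas as pd
import pytest

from msvdq import (
    BranchRule,
    Codebook,
    MissingCategoryMatrix,
    MultiSourceDataset,
    VariableSpec,
    categorize,
    completeness_summary,
    generate,
    paper_replica_config,
    to_categorical_table,
)
from msvdq.missingness import NOT_APPLICABLE, OBSERVED, ORDINARY


def _smoker_codebook():
    return Codebook(
        [
            VariableSpec("smoker", "risk", "categorical", ("no", "yes")),
            VariableSpec(
                "cigs_per_day", "risk", "continuous", (),
                BranchRule("smoker", frozenset({"yes"})),
            ),
        ]
    )


def _ds(cb, rows, sites=None):
    data = pd.DataFrame(rows)
    return MultiSourceDataset(
        data, pd.Series(sites or ["X"] * len(data)), cb
    )


def test_smoker_skip_logic_codes():
    cb = _smoker_codebook()
    ds = _ds(
        cb,
        {
            "smoker": ["no", "yes", "yes", np.nan],
            "cigs_per_day": [np.nan, np.nan, "10", np.nan],
        },
    )
    codes = categorize(ds, cb).codes
    # non-smoker's blank cigarette count is not applicable
    assert codes.loc[0, "cigs_per_day"] == NOT_APPLICABLE
    # smoker who left it blank: ordinary missing
    assert codes.loc[1, "cigs_per_day"] == ORDINARY
    assert codes.loc[2, "cigs_per_day"] == OBSERVED
    # blank parent with ordinary code -> child ordinary by default
    assert codes.loc[3, "smoker"] == ORDINARY
    assert codes.loc[3, "cigs_per_day"] == ORDINARY


def test_fully_answered_row_is_all_observed():
    cb = _smoker_codebook()
    ds = _ds(cb, {"smoker": ["yes"], "cigs_per_day": ["5"]})
    assert (categorize(ds, cb).codes.to_numpy() == OBSERVED).all()


def test_not_applicable_propagates_down_chains():
    cb = Codebook(
        [
            VariableSpec("a", "s", "categorical", ("no", "yes")),
            VariableSpec(
                "b", "s", "categorical", ("no", "yes"),
                BranchRule("a", frozenset({"yes"})),
            ),
            VariableSpec(
                "c", "s", "continuous", (), BranchRule("b", frozenset({"yes"}))
            ),
        ]
    )
    ds = _ds(cb, {"a": ["no"], "b": [np.nan], "c": [np.nan]})
    codes = categorize(ds, cb, cascade="propagate").codes
    assert codes.loc[0, "b"] == NOT_APPLICABLE
    assert codes.loc[0, "c"] == NOT_APPLICABLE  # inherited through blank parent
    conservative = categorize(ds, cb, cascade="ordinary").codes
    assert conservative.loc[0, "b"] == NOT_APPLICABLE
    assert conservative.loc[0, "c"] == ORDINARY


def test_codes_partition_cells_and_ignore_row_order(replica):
    ds, cb = replica
    m = categorize(ds, cb)
    vals = m.codes.to_numpy()
    counts = [(vals == c).sum() for c in (ORDINARY, NOT_APPLICABLE, OBSERVED)]
    assert sum(counts) == 652 * 130
    perm = np.random.default_rng(0).permutation(ds.n)
    shuffled = MultiSourceDataset(
        ds.data.iloc[perm].reset_index(drop=True),
        ds.site.iloc[perm].reset_index(drop=True),
        cb,
    )
    m2 = categorize(shuffled, cb)
    np.testing.assert_array_equal(m2.codes.to_numpy(), vals[perm])


def test_summary_reproduces_study_category_shares():
    """A matrix with the study's printed counts (70,384 / 6,260 / 8,116 of
    84,760) yields shares 83.0 / 7.4 / 9.6 and whole-percent 83."""
    n, p = 652, 130
    flat = np.concatenate(
        [
            np.full(8116, ORDINARY),
            np.full(6260, NOT_APPLICABLE),
            np.full(70_384, OBSERVED),
        ]
    )
    codes = pd.DataFrame(
        flat.reshape(n, p), columns=[f"Q{j+1}" for j in range(p)]
    )
    m = MissingCategoryMatrix(
        codes=codes,
        site=pd.Series(["X"] * n),
        sections={c: "s" for c in codes.columns},
    )
    s = completeness_summary(m)
    assert s.total_cells == 84_760
    assert s.percents == {"ordinary": 9.6, "not_applicable": 7.4, "observed": 83.0}
    assert s.complete_percent_whole == 83


def test_summary_site_section_slice_shares():
    """One site with 100 missing of 1,576 cells in a section -> 6.3%; the
    complementary 10 of 3,640 -> 0.3% (the study's quality-of-life split)."""
    section_p = 8
    rows_es, rows_other = 197, 455
    codes_es = np.full((rows_es, section_p), OBSERVED)
    codes_es.ravel()[:100] = ORDINARY  # 100 of 1576
    codes_other = np.full((rows_other, section_p), OBSERVED)
    codes_other.ravel()[:10] = ORDINARY  # 10 of 3640
    codes = pd.DataFrame(
        np.vstack([codes_es, codes_other]),
        columns=[f"Q{j}" for j in range(section_p)],
    )
    m = MissingCategoryMatrix(
        codes=codes,
        site=pd.Series(["ES"] * rows_es + ["OTHER"] * rows_other),
        sections={c: "quality of life" for c in codes.columns},
    )
    s = completeness_summary(m)
    es = s.by_site_section.loc[("ES", "quality of life")]
    other = s.by_site_section.loc[("OTHER", "quality of life")]
    assert es["ordinary_n"] == 100 and es["ordinary_pct"] == 6.3
    assert other["ordinary_n"] == 10 and other["ordinary_pct"] == 0.3


def test_to_categorical_table_flags_and_levels(replica):
    all2 = MissingCategoryMatrix(
        codes=pd.DataFrame(OBSERVED, index=range(4), columns=["a", "b"]),
        site=pd.Series(["X"] * 4),
        sections={"a": "s", "b": "s"},
    )
    table, constant = to_categorical_table(all2)
    assert constant == ["a", "b"]
    assert set(table.to_numpy().ravel()) == {"observed"}

    ds, cb = replica
    table_r, _ = to_categorical_table(categorize(ds, cb))
    frac_na = (table_r.to_numpy() == "not_applicable").mean() * 100
    assert abs(frac_na - 7.4) <= 1.5


def test_code1_matches_generator_truth_where_parents_observed():
    """Across 10 seeded replicas, not-applicable codes equal the generator's
    structural-blank set exactly on cells whose parent is observed."""
    for seed in range(10):
        ds, cb, truth = generate(paper_replica_config(seed=200 + seed))
        codes = categorize(ds, cb).codes
        for spec in cb:
            if spec.branch_rule is None:
                assert not (codes[spec.id] == NOT_APPLICABLE).any()
                continue
            parent_obs = ds.data[spec.branch_rule.parent_id].notna().to_numpy()
            got = (codes[spec.id].to_numpy() == NOT_APPLICABLE)[parent_obs]
            want = truth.structural_blanks[spec.id].to_numpy()[parent_obs]
            np.testing.assert_array_equal(got, want)
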