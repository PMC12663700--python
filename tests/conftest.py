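import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from msvdq import (
    BranchRule,
    Codebook,
    MultiSourceDataset,
    ShiftSpec,
    VariableSpec,
    generate,
    make_paper_replica,
    paper_replica_config,
    run_completeness_analysis,
    run_values_analysis,
)


@pytest.fixture
def tiny_codebook() -> Codebook:
    """Four questions incl. one branch-gated continuous and one text item."""
    return Codebook(
        [
            VariableSpec("Q1", "habits", "categorical", ("no", "yes")),
            VariableSpec(
                "Q2", "habits", "continuous", (), BranchRule("Q1", frozenset({"yes"}))
            ),
            VariableSpec("Q3", "habits", "text"),
            VariableSpec(
                "Q4", "wellbeing", "ordinal", ("never", "sometimes", "often")
            ),
        ]
    )


@pytest.fixture
def tiny_dataset(tiny_codebook) -> MultiSourceDataset:
    data = pd.DataFrame(
        {
            "Q1": ["yes", "no", "yes", np.nan],
            "Q2": ["12.5", np.nan, "3.0", np.nan],
            "Q3": ["fine", np.nan, "ok", "meh"],
            "Q4": ["often", "never", np.nan, "sometimes"],
        }
    )
    return MultiSourceDataset(
        data=data, site=pd.Series(["A", "A", "B", "B"]), codebook=tiny_codebook
    )


@pytest.fixture(scope="session")
def replica():
    """The fixed study-scale scenario (652 x 130, 4 sites, 9 sections)."""
    return make_paper_replica()


@pytest.fixture(scope="session")
def replica_truth():
    return generate(paper_replica_config())


@pytest.fixture(scope="session")
def recovery_results():
    """Runs the 20-seed recovery experiment once for both branches.

    Each run: the study-scale replica with site C additionally shifted by
    2 SD in the health-literacy section (values branch probe) while keeping
    the replica's concentrated site-C missingness (completeness probe).
    Returns hit counts of 'site C attains the maximum SPO' for each branch.
    """
    hits_values = 0
    hits_completeness = 0
    n_runs = 20
    for seed in range(100, 100 + n_runs):
        cfg = paper_replica_config(seed=seed)
        shifts = dict(cfg.shifts)
        shifts["C"] = ShiftSpec(
            ("health literacy",) + shifts["C"].sections, 2.0, shifts["C"].alpha
        )
        cfg = replace(cfg, shifts=shifts)
        ds, cb, _ = generate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rv = run_values_analysis(ds, cb, section="health literacy")
            rc = run_completeness_analysis(
                ds, cb, section="interpersonal communication"
            )
        if max(rv.msv.spo, key=rv.msv.spo.get) == "C":
            hits_values += 1
        if max(rc.msv.spo, key=rc.msv.spo.get) == "C":
            hits_completeness += 1
    return {"values": hits_values, "completeness": hits_completeness, "n": n_runs}
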