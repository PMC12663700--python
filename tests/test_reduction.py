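import warnings

import numpy as np
import pandas as pd
import pytest

from msvdq import (
    EncodedMatrix,
    SectionSpec,
    ShiftSpec,
    SimulationConfig,
    encode,
    generate,
    mca_reduce,
    pca_reduce,
    top_contributors,
)


def _complete(values, columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"x{j}" for j in range(values.shape[1])]
    return EncodedMatrix(
        values=values,
        mask=np.zeros(values.shape, dtype=bool),
        columns=columns,
        encoders={c: () for c in columns},
        site=np.array(["A"] * values.shape[0]),
    )


# ---------------------------------------------------------------- PCA


def test_pca_perfectly_correlated_pair_explains_everything():
    x = np.random.default_rng(0).normal(size=100)
    r = pca_reduce(_complete(np.column_stack([x, x])), k=1)
    assert r.explained[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_isotropic_explained_fractions():
    rng = np.random.default_rng(1)
    r = pca_reduce(_complete(rng.normal(size=(3000, 10))), k=3)
    # eigenvalues of isotropic covariance are ~equal: each fraction ~0.1
    assert np.all(np.abs(r.explained - 0.1) < 0.04)
    assert r.explained.sum() < 0.45


def test_pca_loadings_orthonormal_and_variance_identity():
    rng = np.random.default_rng(2)
    r = pca_reduce(_complete(rng.normal(size=(80, 6)) @ rng.normal(size=(6, 6))), k=3)
    L = r.loadings.to_numpy()
    np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-10)
    score_var = r.scores.var(axis=0, ddof=1).sum()
    assert score_var == pytest.approx(float(r.eigenvalues.sum()), abs=1e-8)
    # explained fractions non-negative, non-increasing, sum <= 1
    assert (r.explained >= 0).all()
    assert (np.diff(r.explained) <= 1e-12).all()
    assert r.explained.sum() <= 1 + 1e-12


def test_pca_deterministic_sign_convention_and_sklearn_cross_check():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 5)) @ np.diag([3, 2, 1, 0.5, 0.2])
    runs = [pca_reduce(_complete(X.copy()), k=3) for _ in range(2)]
    np.testing.assert_array_equal(runs[0].scores, runs[1].scores)
    for a in range(3):
        col = runs[0].loadings.to_numpy()[:, a]
        assert col[np.argmax(np.abs(col))] > 0

    from sklearn.decomposition import PCA

    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    sk = PCA(n_components=3).fit(Xs)
    np.testing.assert_allclose(
        np.abs(runs[0].loadings.to_numpy().T), np.abs(sk.components_), atol=1e-8
    )


def test_pca_drops_zero_variance_column_with_warning():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 3))
    X[:, 1] = 5.0
    with pytest.warns(UserWarning, match="zero-variance"):
        r = pca_reduce(_complete(X), k=2)
    assert r.feature_names == ["x0", "x2"]
    assert r.dropped == ["x1"]


# ---------------------------------------------------------------- MCA


def _ca_oracle(table: pd.DataFrame, k: int):
    """Brute-force CA of the indicator matrix by direct eigen-decomposition."""
    Z = pd.get_dummies(table, prefix_sep="=").to_numpy(dtype=float)
    P = Z / Z.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    # eigen-decomposition of S S^T gives U and the squared singular values
    evals, U = np.linalg.eigh(S @ S.T)
    order = np.argsort(evals)[::-1]
    evals, U = np.clip(evals[order], 0, None), U[:, order]
    coords = U[:, :k] * np.sqrt(evals[:k]) / np.sqrt(r)[:, None]
    return coords, evals


def test_mca_equal_profiles_map_together():
    table = pd.DataFrame(
        {
            "a": ["x", "x", "y", "y", "x", "y"],
            "b": ["x", "x", "y", "y", "x", "y"],
        }
    )
    r = mca_reduce(table, k=1)
    # rows 0,1,4 share a profile, as do 2,3,5
    np.testing.assert_allclose(r.scores[0], r.scores[1], atol=1e-10)
    np.testing.assert_allclose(r.scores[2], r.scores[5], atol=1e-10)
    assert abs(r.scores[0, 0] - r.scores[2, 0]) > 0.1


def test_mca_independent_balanced_table_has_flat_spectrum():
    """For the indicator-matrix dialect, a balanced independent p=2 table
    has all non-trivial inertias equal to 1/p: no axis is preferred."""
    table = pd.DataFrame(
        {"u": ["a", "a", "b", "b"], "v": ["x", "y", "x", "y"]}
    )
    r = mca_reduce(table, k=2)
    np.testing.assert_allclose(r.eigenvalues, 0.5, atol=1e-12)
    np.testing.assert_allclose(r.explained, 0.5, atol=1e-12)
    # the four distinct profiles sit at the vertices of a square
    from scipy.spatial.distance import pdist

    d = np.sort(pdist(r.scores))
    np.testing.assert_allclose(d[:4], d[0], atol=1e-10)
    np.testing.assert_allclose(d[4:], d[0] * np.sqrt(2.0), atol=1e-10)


def test_mca_matches_direct_eigen_oracle():
    rng = np.random.default_rng(5)
    table = pd.DataFrame(
        {
            "q1": rng.choice(["a", "b", "c"], size=40),
            "q2": rng.choice(["x", "y"], size=40),
            "q3": rng.choice(["l", "m", "h"], size=40),
        }
    )
    k = 2
    r = mca_reduce(table, k=k)
    coords, _ = _ca_oracle(table, k)
    np.testing.assert_allclose(np.abs(r.scores), np.abs(coords), atol=1e-8)
    # explained inertia fractions sum to <= 1
    assert r.explained.sum() <= 1 + 1e-12


def test_mca_drops_constant_column():
    table = pd.DataFrame(
        {"c": ["same"] * 10, "v": ["a", "b"] * 5}
    )
    with pytest.warns(UserWarning, match="constant"):
        r = mca_reduce(table, k=1)
    assert r.dropped == ["c"]
    assert r.feature_names == ["v"]


# ------------------------------------------------------- contributors


def test_top_contributors_dominant_variable_first():
    r = pca_reduce(
        _complete(
            np.column_stack(
                [
                    np.random.default_rng(6).normal(size=50) * 10,
                    np.random.default_rng(7).normal(size=50) * 0.01,
                ]
            ),
            columns=["Q9", "Q2"],
        ),
        k=1,
        standardize=False,
    )
    top = top_contributors(r, 1)
    assert list(top.index) == ["Q9"]


def test_top_contributors_tie_keeps_codebook_order():
    from msvdq.reduce import ReducedScores

    r = ReducedScores(
        scores=np.zeros((4, 1)),
        loadings=pd.DataFrame(),
        explained=np.array([1.0]),
        eigenvalues=np.array([1.0]),
        contributions=pd.Series([0.5, 0.5, 0.2], index=["Qfirst", "Qsecond", "Qlast"]),
        site=np.array(["A"] * 4),
        feature_names=["Qfirst", "Qsecond", "Qlast"],
        method="pca",
    )
    top = top_contributors(r, 3)
    assert list(top.index) == ["Qfirst", "Qsecond", "Qlast"]


def test_top_contributors_overflow_warns_and_returns_all():
    r = pca_reduce(_complete(np.random.default_rng(9).normal(size=(30, 3))), k=2)
    with pytest.warns(UserWarning, match="returning all"):
        top = top_contributors(r, 20)
    assert len(top) == 3


def test_shifted_variables_reach_top20_in_replica_scale_data():
    """With 5 strongly shifted variables among 130, at least 3 appear in the
    PCA top-20 in >=90% of 20 seeded runs."""
    sections = (
        SectionSpec("probe", 5, {"continuous": 1.0}),
        SectionSpec("bulk1", 45, {"continuous": 0.4, "ordinal": 0.3, "categorical": 0.3}),
        SectionSpec("bulk2", 40, {"ordinal": 0.5, "categorical": 0.5}),
        SectionSpec("bulk3", 40, {"continuous": 0.5, "ordinal": 0.5}),
    )
    hits = 0
    for seed in range(20):
        cfg = SimulationConfig(
            sites=(("A", 142), ("B", 158), ("C", 197), ("D", 155)),
            sections=sections,
            shifts={"C": ShiftSpec(("probe",), delta=3.0)},
            seed=seed,
        )
        ds, cb, _ = generate(cfg)
        probe_ids = set(cb.section_ids("probe"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = pca_reduce(encode(ds, cb), k=3)
            top = top_contributors(r, 20)
        if len(probe_ids & set(top.index)) >= 3:
            hits += 1
    assert hits >= 18
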