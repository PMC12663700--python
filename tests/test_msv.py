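import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

from msvdq import (
    AlignedDensity,
    DistanceMatrix,
    MetricError,
    compute_msv,
    embed_simplex,
    js_distance,
    msv_from_densities,
    msv_plot_coords,
    pairwise_distances,
    regular_simplex_radius,
)


def _density(vectors: dict[str, np.ndarray], cases=None) -> AlignedDensity:
    length = len(next(iter(vectors.values())))
    return AlignedDensity(
        densities={k: np.asarray(v, dtype=float) for k, v in vectors.items()},
        bin_edges=[np.arange(length + 1.0)],
        n_cases=cases or {k: 10 for k in vectors},
    )


def _random_density(rng, length):
    v = rng.dirichlet(np.ones(length))
    return v / v.sum()


# ------------------------------------------------------------ distance


def test_js_distance_identity_and_disjoint():
    p = np.array([0.2, 0.3, 0.5])
    assert js_distance(p, p) == 0.0
    assert js_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(
        1.0, abs=1e-12
    )


def test_js_distance_half_vs_point_mass():
    # 0.5*KL((.5,.5)||(.75,.25)) + 0.5*KL((1,0)||(.75,.25)) = 0.311278
    d = js_distance(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
    assert d == pytest.approx(0.557923, abs=1e-6)


def test_js_distance_matches_scipy_and_is_symmetric():
    rng = np.random.default_rng(0)
    for _ in range(25):
        p, q = _random_density(rng, 16), _random_density(rng, 16)
        ours = js_distance(p, q)
        assert ours == pytest.approx(js_distance(q, p), abs=1e-15)
        assert ours == pytest.approx(float(jensenshannon(p, q, base=2)), abs=1e-12)


def test_js_distance_rejects_bad_input():
    with pytest.raises(MetricError, match="length"):
        js_distance(np.array([1.0]), np.array([0.5, 0.5]))
    with pytest.raises(MetricError, match="negative"):
        js_distance(np.array([1.5, -0.5]), np.array([0.5, 0.5]))
    with pytest.raises(MetricError, match="sum to 1"):
        js_distance(np.array([0.4, 0.4]), np.array([0.5, 0.5]))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_js_distance_triangle_inequality(seed):
    rng = np.random.default_rng(seed)
    p, q, r = (_random_density(rng, 12) for _ in range(3))
    assert js_distance(p, r) <= js_distance(p, q) + js_distance(q, r) + 1e-12


# ------------------------------------------------------------ pairwise


def test_pairwise_identical_and_mixed_sources():
    p = np.array([0.5, 0.5, 0.0])
    dm = pairwise_distances(_density({"A": p, "B": p}))
    np.testing.assert_array_equal(dm.values, np.zeros((2, 2)))

    q = np.array([0.0, 0.0, 1.0])
    dm = pairwise_distances(_density({"A": p, "B": p, "C": q}))
    offdiag = sorted(dm.values[np.triu_indices(3, 1)])
    np.testing.assert_allclose(offdiag, [0.0, 1.0, 1.0], atol=1e-12)
    np.testing.assert_array_equal(dm.values, dm.values.T)


def test_pairwise_needs_two_sources():
    with pytest.raises(MetricError, match=">=2"):
        pairwise_distances(_density({"A": np.array([1.0])}))


# ------------------------------------------------------------ simplex


def test_two_sources_at_unit_distance_embed_at_half():
    dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["A", "B"])
    e = embed_simplex(dm)
    np.testing.assert_allclose(np.sort(e.coords[:, 0]), [-0.5, 0.5], atol=1e-12)
    np.testing.assert_allclose(e.centroid, 0.0, atol=1e-12)


def test_identical_sources_embed_at_origin():
    dm = DistanceMatrix(np.zeros((5, 5)), list("ABCDE"))
    e = embed_simplex(dm)
    np.testing.assert_allclose(e.coords, 0.0)
    np.testing.assert_allclose(e.centroid, 0.0)


def test_four_disjoint_sources_form_regular_tetrahedron():
    dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("ABCD"))
    e = embed_simplex(dm)
    d = np.linalg.norm(e.coords - e.centroid, axis=1)
    np.testing.assert_allclose(d, np.sqrt(3.0 / 8.0), atol=1e-9)
    assert regular_simplex_radius(4) == pytest.approx(np.sqrt(3.0 / 8.0))


def test_embedding_reproduces_random_sqrt_jsd_matrices():
    rng = np.random.default_rng(1)
    for s in (3, 5, 8):
        dens = {f"S{i}": _random_density(rng, 20) for i in range(s)}
        dm = pairwise_distances(_density(dens))
        e = embed_simplex(dm)
        recon = np.sqrt(
            ((e.coords[:, None, :] - e.coords[None, :, :]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(recon, dm.values, atol=1e-8)


def test_embedding_cross_checks_against_skbio_pcoa():
    import skbio

    rng = np.random.default_rng(2)
    dens = {f"S{i}": _random_density(rng, 15) for i in range(5)}
    dm = pairwise_distances(_density(dens))
    e = embed_simplex(dm)
    ours = np.sort(np.linalg.norm(e.coords - e.coords.mean(0), axis=1))
    res = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.values))
    pts = res.samples.to_numpy()
    theirs = np.sort(np.linalg.norm(pts - pts.mean(0), axis=1))
    np.testing.assert_allclose(ours, theirs, atol=1e-8)


def test_non_euclidean_matrix_is_rejected():
    # gross triangle-inequality violation cannot come from sqrt-JSD vectors
    v = np.array([[0.0, 1.0, 0.05], [1.0, 0.0, 0.05], [0.05, 0.05, 0.0]])
    with pytest.raises(MetricError, match="embeddable"):
        embed_simplex(DistanceMatrix(v, list("ABC")))


# ------------------------------------------------------------ metrics


def test_metric_endpoints():
    p = np.array([0.25, 0.25, 0.25, 0.25])
    res = msv_from_densities(_density({s: p.copy() for s in "ABCD"}))
    assert res.gpd == pytest.approx(0.0, abs=1e-9)
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in res.spo.values())

    eye = np.eye(4)
    res2 = msv_from_densities(_density({s: eye[i] for i, s in enumerate("ABCD")}))
    assert res2.gpd == pytest.approx(1.0, abs=1e-9)
    eye2 = np.eye(2)
    res3 = msv_from_densities(_density({s: eye2[i] for i, s in enumerate("AB")}))
    assert res3.gpd == pytest.approx(1.0, abs=1e-9)
    assert all(v == pytest.approx(1.0, abs=1e-9) for v in res3.spo.values())


def test_gpd_invariant_to_relabeling_and_bin_permutation():
    rng = np.random.default_rng(3)
    dens = {s: _random_density(rng, 12) for s in "ABCD"}
    cases = {"A": 30, "B": 40, "C": 50, "D": 20}
    base = msv_from_densities(_density(dens, cases))
    perm = rng.permutation(12)
    permuted = {s: v[perm] for s, v in dens.items()}
    res_perm = msv_from_densities(_density(permuted, cases))
    assert res_perm.gpd == pytest.approx(base.gpd, abs=1e-12)
    renamed = {f"Z{s}": dens[s] for s in "ABCD"}
    res_ren = msv_from_densities(
        _density(renamed, {f"Z{s}": cases[s] for s in "ABCD"})
    )
    assert res_ren.gpd == pytest.approx(base.gpd, abs=1e-12)


def test_gpd_monotone_in_gaussian_mean_gap():
    from msvdq import build_density

    rng = np.random.default_rng(4)
    base = rng.normal(size=600)
    noise = rng.normal(size=600)
    gpds = []
    for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
        pts = {"A": base[:, None], "B": (noise + delta)[:, None]}
        ad = build_density(pts, bins_per_dim=10)
        gpds.append(msv_from_densities(ad).gpd)
    assert all(b >= a - 1e-12 for a, b in zip(gpds, gpds[1:]))
    assert gpds[-1] > gpds[0]


def test_spo_clipped_in_unequal_weight_corner():
    eye = np.eye(2)
    res = msv_from_densities(
        _density({"heavy": eye[0], "light": eye[1]}, {"heavy": 1000, "light": 2})
    )
    assert 0.0 <= res.spo["light"] <= 1.0
    assert 0.0 <= res.gpd <= 1.0


def test_plot_coords_padding_radii_and_equilateral_geometry():
    dm2 = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
    with pytest.warns(UserWarning, match="zero-padding"):
        coords, radii = msv_plot_coords(embed_simplex(dm2), dims=2)
    np.testing.assert_allclose(coords[:, 1], 0.0)
    assert radii == {"A": 1.0, "B": 1.0}

    d = 0.2
    dm3 = DistanceMatrix(d * (np.ones((3, 3)) - np.eye(3)), list("ABC"))
    coords3, _ = msv_plot_coords(embed_simplex(dm3), dims=2)
    sides = [
        np.linalg.norm(coords3[i] - coords3[j]) for i, j in ((0, 1), (0, 2), (1, 2))
    ]
    np.testing.assert_allclose(sides, d, atol=1e-8)
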