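"""Multisource variability metrics on aligned probability densities.

Sources are compared pairwise with the Jensen–Shannon *distance* (the
square root of the base-2 Jensen–Shannon divergence, a metric bounded by
1).  The distance matrix is embedded as the vertices of a simplex by
classical (Torgerson) multidimensional scaling — √JSD matrices are
Hilbertian, so the embedding is essentially exact — and the case-count-
weighted centroid of the vertices acts as the informed average
distribution.  Two summary metrics follow, both in [0, 1]:

* **SPO** (source probabilistic outlyingness): each vertex's distance to
  the centroid, normalized by the vertex–centroid distance
  c_s = sqrt((s-1)/(2s)) of the unit-edge regular simplex — the
  maximal-separation configuration.  0 means the source sits on the
  average distribution.
* **GPD** (global probabilistic deviation): the weighted mean of the
  vertex–centroid distances under the same normalization.  0 means all
  sources are identically distributed; 1 means pairwise non-overlapping
  supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import MetricError
from .densities import AlignedDensity


def regular_simplex_radius(s: int) -> float:
    """Vertex-to-centroid distance of the unit-edge regular (s-1)-simplex."""
    return float(np.sqrt((s - 1) / (2.0 * s)))


def js_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon distance between two probability vectors.

    sqrt( 0.5*KL(p||m) + 0.5*KL(q||m) ) with m = (p+q)/2, base-2
    logarithms and the convention 0*log 0 = 0; symmetric and in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise MetricError("length mismatch between probability vectors")
    if (p < 0).any() or (q < 0).any():
        raise MetricError("negative probability mass")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise MetricError("probability vectors must sum to 1")
    m = 0.5 * (p + q)
    div = 0.5 * _kl2(p, m) + 0.5 * _kl2(q, m)
    return float(np.sqrt(min(max(div, 0.0), 1.0)))


def _kl2(p: np.ndarray, m: np.ndarray) -> float:
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / m[nz])))


@dataclass
class DistanceMatrix:
    """Symmetric matrix of Jensen–Shannon distances, zero diagonal."""

    values: np.ndarray
    sources: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sources):
            raise MetricError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12) or np.abs(np.diag(v)).max() > 1e-12:
            raise MetricError("distance matrix must be symmetric with zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-9:
            raise MetricError("Jensen-Shannon distances must lie in [0, 1]")
        self.values = v

    @property
    def s(self) -> int:
        return len(self.sources)


def pairwise_distances(d: AlignedDensity) -> DistanceMatrix:
    """All pairwise Jensen–Shannon distances between the sources."""
    sources = d.sources
    if len(sources) < 2:
        raise MetricError("need >=2 sources")
    s = len(sources)
    out = np.zeros((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            out[i, j] = out[j, i] = js_distance(
                d.densities[sources[i]], d.densities[sources[j]]
            )
    return DistanceMatrix(values=out, sources=list(sources))


@dataclass
class SimplexEmbedding:
    """Torgerson embedding of the sources plus the informed centroid."""

    coords: np.ndarray  # s x (s-1)
    sources: list[str]
    weights: np.ndarray
    centroid: np.ndarray
    eigenvalues: np.ndarray
    distances: DistanceMatrix | None = field(default=None, repr=False)

    @property
    def s(self) -> int:
        return len(self.sources)


def embed_simplex(
    dm: DistanceMatrix, weights: np.ndarray | None = None
) -> SimplexEmbedding:
    """Classical multidimensional scaling of a √JSD distance matrix.

    B = -1/2 J D² J with J the centering matrix; eigen-decompose B; the
    coordinates are eigenvectors scaled by the square roots of the
    (clipped) non-negative eigenvalues.  √JSD matrices embed exactly in
    Euclidean space, so a strongly negative eigenvalue (magnitude beyond
    1e-6 of the largest) signals corrupted input and raises.  The centroid
    is the ``weights``-weighted mean of the vertices (case counts; equal
    weights when omitted).
    """
    s = dm.s
    if weights is None:
        weights = np.ones(s)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (s,) or (weights <= 0).any():
        raise MetricError("weights must be positive, one per source")
    D2 = dm.values**2
    J = np.eye(s) - np.full((s, s), 1.0 / s)
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)  # symmetrize against round-off
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    top = max(evals.max(), 0.0)
    if top > 0 and evals.min() < -1e-6 * top:
        raise MetricError(
            "distance matrix is not Euclidean-embeddable (strongly negative "
            "eigenvalue); input densities are likely corrupted"
        )
    evals = np.where(evals > 0, evals, 0.0)
    k = s - 1
    coords = (evecs[:, :k] * np.sqrt(evals[:k])).copy()
    for a in range(coords.shape[1]):  # deterministic sign convention
        j = int(np.argmax(np.abs(coords[:, a])))
        if coords[j, a] < 0:
            coords[:, a] *= -1.0
    centroid = weights @ coords / weights.sum()
    return SimplexEmbedding(
        coords=coords,
        sources=list(dm.sources),
        weights=weights,
        centroid=centroid,
        eigenvalues=evals[:k],
        distances=dm,
    )


@dataclass
class MSVResult:
    """GPD, per-source SPO, and the data behind the MSV plot."""

    gpd: float
    spo: dict[str, float]
    distances: DistanceMatrix | None
    plot_coords: np.ndarray
    radii: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gpd": self.gpd,
            "spo": dict(self.spo),
            "distances": None
            if self.distances is None
            else {
                "sources": self.distances.sources,
                "values": self.distances.values.tolist(),
            },
            "plot": {
                "coords": self.plot_coords.tolist(),
                "radii": dict(self.radii),
            },
            "flags": list(self.flags),
        }


def compute_msv(e: SimplexEmbedding, plot_dims: int = 2) -> MSVResult:
    """SPO per source and GPD from a simplex embedding.

    With d_i the Euclidean distance of vertex i to the centroid and
    c_s = sqrt((s-1)/(2s)):  SPO_i = min(1, d_i / c_s) and
    GPD = min(1, (Σ w_i d_i / Σ w_i) / c_s).  The clip guards the
    unequal-weight corner where a light source can sit beyond c_s.
    """
    if e.s < 2:
        raise MetricError("need >=2 sources")
    c_s = regular_simplex_radius(e.s)
    d = np.linalg.norm(e.coords - e.centroid, axis=1)
    spo = {src: min(1.0, float(di / c_s)) for src, di in zip(e.sources, d)}
    gpd = min(1.0, float((e.weights @ d) / e.weights.sum() / c_s))
    coords, radii = msv_plot_coords(e, dims=plot_dims)
    return MSVResult(
        gpd=gpd,
        spo=spo,
        distances=e.distances,
        plot_coords=coords,
        radii=radii,
    )


def msv_plot_coords(
    e: SimplexEmbedding, dims: int = 2, r_max: float = 1.0
) -> tuple[np.ndarray, dict[str, float]]:
    """MSV-plot coordinates: the ``dims`` highest-eigenvalue axes, plus a
    radius per source proportional to its case count (r_max for the
    largest source).  Missing axes are padded with zeros."""
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    available = e.coords.shape[1]
    if dims > available:
        warnings.warn(f"only {available} embedding axes available; zero-padding")
    coords = np.zeros((e.s, dims))
    take = min(dims, available)
    coords[:, :take] = e.coords[:, :take]
    wmax = e.weights.max()
    radii = {src: float(r_max * w / wmax) for src, w in zip(e.sources, e.weights)}
    return coords, radii


def msv_from_densities(
    d: AlignedDensity,
    weights: np.ndarray | None = None,
    weighted_centroid: bool = True,
) -> MSVResult:
    """Full metric chain: pairwise √JSD -> simplex -> SPO/GPD.

    ``weights`` defaults to the per-source retained case counts; pass
    ``weighted_centroid=False`` for the unweighted centroid variant.
    """
    dm = pairwise_distances(d)
    if weights is None:
        weights = np.array([d.n_cases[s] for s in d.sources], dtype=float)
    if not weighted_centroid:
        weights = np.ones(len(d.sources))
    e = embed_simplex(dm, weights)
    return compute_msv(e)
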