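"""Aligned histogram densities: each site's distribution fingerprint.

Every site's (filtered, reduced) point cloud is binned on a grid shared by
all sites — per dimension, equally spaced edges spanning the pooled
min..max, upper edge inclusive — then flattened in row-major order and
normalized to sum to 1.  Sharing the grid is what makes Jensen–Shannon
distances between the resulting vectors meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np


@dataclass
class AlignedDensity:
    """Per-source probability vectors over one shared flattened bin grid."""

    densities: dict[str, np.ndarray]
    bin_edges: list[np.ndarray]
    n_cases: dict[str, int]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.densities.values()}
        if len(lengths) > 1:
            raise ValueError("sources have different vector lengths")
        for src, vec in self.densities.items():
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-12:
                raise ValueError(f"source {src!r}: not a probability vector")

    @property
    def sources(self) -> list[str]:
        return list(self.densities)

    @property
    def vector_length(self) -> int:
        return len(next(iter(self.densities.values())))

    def stacked(self) -> np.ndarray:
        """Column-stacked matrix (bins x sources), export form."""
        return np.column_stack([self.densities[s] for s in self.sources])


def shared_edges(
    points_by_source: Mapping[str, np.ndarray], bins_per_dim: int = 10
) -> list[np.ndarray]:
    """Per-dimension bin edges spanning the pooled range of all sources.

    A dimension with zero pooled range collapses to a single unit-width bin
    centred on the constant value (with a warning).
    """
    arrays = [np.atleast_2d(np.asarray(p, dtype=float)) for p in points_by_source.values()]
    if not arrays or sum(a.shape[0] for a in arrays) == 0:
        raise ValueError("need at least one point overall")
    pooled = np.vstack(arrays)
    if not np.isfinite(pooled).all():
        raise ValueError("non-finite coordinates")
    edges = []
    for d in range(pooled.shape[1]):
        lo, hi = pooled[:, d].min(), pooled[:, d].max()
        if hi == lo:
            warnings.warn(f"dimension {d}: zero range, collapsing to one bin")
            edges.append(np.array([lo - 0.5, hi + 0.5]))
        else:
            edges.append(np.linspace(lo, hi, bins_per_dim + 1))
    return edges


def histogram_source(points: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    """Flattened, normalized histogram of one source on the shared grid.

    Points outside the edge bounds are clamped in (with a warning); the
    upper edge of each dimension is inclusive (numpy's histogramdd rule).
    Flattening is row-major so vectors are comparable across runs.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = points.shape[0]
    if m == 0:
        raise ValueError("empty source")
    lo = np.array([e[0] for e in edges])
    hi = np.array([e[-1] for e in edges])
    if (points < lo).any() or (points > hi).any():
        warnings.warn("points outside the shared grid were clamped to its bounds")
        points = np.clip(points, lo, hi)
    counts, _ = np.histogramdd(points, bins=edges)
    return counts.ravel(order="C") / m


def build_density(
    points_by_source: Mapping[str, np.ndarray], bins_per_dim: int = 10
) -> AlignedDensity:
    """Shared edges + per-source histograms in one step."""
    edges = shared_edges(points_by_source, bins_per_dim)
    densities = {
        src: histogram_source(p, edges) for src, p in points_by_source.items()
    }
    n_cases = {
        src: int(np.atleast_2d(np.asarray(p)).shape[0])
        for src, p in points_by_source.items()
    }
    return AlignedDensity(densities=densities, bin_edges=edges, n_cases=n_cases)
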