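"""Per-site outlier removal in the reduced space via the local outlier factor.

LOF compares each point's local reachability density with that of its
k-distance neighborhood; scores near 1 mean inlier, markedly larger scores
mean the point sits in a sparser region than its neighbors.  Filtering is
done within each site independently, so an entire site that differs from
the others is never trimmed away — only points atypical *for their own
site* are removed, and never more than a configurable fraction of a site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .reduce import ReducedScores

#: floor for local-reachability-density denominators so coincident points
#: (zero distances everywhere) yield finite, equal scores of 1
_LRD_FLOOR = 1e-12


@dataclass
class OutlierReport:
    kept_index: dict[str, np.ndarray]  # per-site global row indices retained
    lof_scores: np.ndarray  # per-row score, full dataset order
    threshold: float
    k_neighbors: int
    capped_excess: dict[str, int] = field(default_factory=dict)

    @property
    def removed_index(self) -> dict[str, np.ndarray]:
        out = {}
        all_kept = {i for idx in self.kept_index.values() for i in idx}
        for site, kept in self.kept_index.items():
            site_rows = self._site_rows.get(site)
            out[site] = np.array([i for i in site_rows if i not in all_kept])
        return out

    _site_rows: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def lof_scores(points: np.ndarray, k_neighbors: int) -> np.ndarray:
    """Local outlier factor of every point (Euclidean metric).

    Uses the k-distance neighborhood (all points within the k-th nearest
    distance, so ties enlarge the neighborhood), reachability distance
    reach_k(a,b) = max(k-dist(b), d(a,b)), local reachability density
    lrd(a) = 1 / mean reach over the neighborhood, and
    LOF(a) = mean(lrd(neighbor)) / lrd(a).  ``k_neighbors`` is truncated to
    m-1 when it is not smaller than the sample.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = points.shape[0]
    if m < 2:
        raise ValueError("LOF needs at least 2 points")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    k = min(k_neighbors, m - 1)
    dist = cdist(points, points)
    np.fill_diagonal(dist, np.inf)
    kdist = np.partition(dist, k - 1, axis=1)[:, k - 1]
    neighborhoods = [np.flatnonzero(dist[i] <= kdist[i]) for i in range(m)]
    lrd = np.empty(m)
    for i, nb in enumerate(neighborhoods):
        reach = np.maximum(kdist[nb], dist[i, nb])
        lrd[i] = 1.0 / max(reach.mean(), _LRD_FLOOR)
    scores = np.empty(m)
    for i, nb in enumerate(neighborhoods):
        scores[i] = (lrd[nb] / lrd[i]).mean()
    return scores


def filter_per_site(
    r: ReducedScores,
    k_neighbors: int = 20,
    threshold: float = 1.5,
    max_removed_frac: float = 0.10,
) -> tuple[ReducedScores, OutlierReport]:
    """Remove, within each site, points whose LOF exceeds ``threshold``.

    At most ``max_removed_frac`` of a site's rows are ever removed; when
    more points exceed the threshold, the largest scores go first and the
    excess count is flagged in the report.
    """
    site = np.asarray(r.site)
    all_scores = np.full(r.n, np.nan)
    kept_index: dict[str, np.ndarray] = {}
    site_rows: dict[str, np.ndarray] = {}
    capped: dict[str, int] = {}
    labels = list(dict.fromkeys(site))
    for label in labels:
        rows = np.flatnonzero(site == label)
        site_rows[label] = rows
        if len(rows) < 2:
            raise ValueError(f"site {label!r} has fewer than 2 rows")
        scores = lof_scores(r.scores[rows], k_neighbors)
        all_scores[rows] = scores
        over = np.flatnonzero(scores > threshold)
        cap = int(np.floor(max_removed_frac * len(rows)))
        if len(over) > cap:
            capped[label] = len(over) - cap
            order = np.argsort(-scores[over], kind="stable")
            over = over[order[:cap]]
        keep_local = np.setdiff1d(np.arange(len(rows)), over)
        if len(keep_local) < 2:
            raise ValueError(f"site {label!r} reduced below 2 rows by filtering")
        kept_index[label] = rows[keep_local]
    kept_all = np.sort(np.concatenate([kept_index[s] for s in labels]))
    report = OutlierReport(
        kept_index=kept_index,
        lof_scores=all_scores,
        threshold=threshold,
        k_neighbors=k_neighbors,
        capped_excess=capped,
        _site_rows=site_rows,
    )
    return r.restrict_rows(kept_all), report
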