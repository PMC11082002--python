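"""Beta diversity: Bray-Curtis distances, NMDS, permutation tests, zonation, KDE.

ANOSIM and PERMANOVA are implemented with an explicit seeded permutation
loop using the (b+1)/(m+1) p-value estimator, so results are reproducible
from a single integer seed.  Zonation is CONISS-style: agglomerative
clustering restricted to stratigraphically adjacent clusters, with
within-cluster dispersion computed from squared Bray-Curtis dissimilarities;
the two-state cut is the exhaustive minimal-dispersion contiguous split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .tables_io import CommunityMatrix


@dataclass
class DistanceMatrix:
    sample_ids: list
    d: np.ndarray  # square symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # columns NMDS1, NMDS2, ...
    stress: float
    converged: bool
    seed: int


@dataclass
class Zonation:
    """Merge tree over adjacent clusters plus a two-state contiguous cut."""
    merges: list  # (left_start, boundary, right_end, cost) per merge, sample-index based
    heights: np.ndarray  # cumulative dispersion at each merge
    labels: np.ndarray  # 1 for the older state, 2 for the younger
    boundary: int  # first sample index of state 2


def bray_curtis(matrix: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = 1 - 2 sum(min) / sum(x + y)."""
    d = squareform(pdist(matrix.rel.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(sample_ids=matrix.sample_ids, d=d)


def nmds(dist: DistanceMatrix, k: int = 2, restarts: int = 20, seed: int = 0,
         ages=None, max_iter: int = 500) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``restarts`` starts.

    Axis-sign convention: when ``ages`` is given, NMDS1 is flipped so its
    Pearson correlation with sample age is non-negative (the axis sign of an
    NMDS solution is arbitrary, but downstream the NMDS1 score is used as the
    community state variable over time).
    """
    if dist.n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for a {k}-D ordination")
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                init="random", n_init=restarts, max_iter=max_iter, eps=1e-9,
                random_state=int(seed), normalized_stress=True)
    coords = model.fit_transform(dist.d)
    coords = coords - coords.mean(axis=0)
    if ages is not None:
        age = np.asarray(ages, dtype=float)
        for j in range(k):
            r = np.corrcoef(coords[:, j], age)[0, 1]
            if np.isfinite(r) and r < 0:
                coords[:, j] = -coords[:, j]
    converged = bool(model.n_iter_ < max_iter)
    frame = pd.DataFrame(coords, index=dist.sample_ids,
                         columns=[f"NMDS{j + 1}" for j in range(k)])
    return OrdinationResult(coordinates=frame, stress=float(model.stress_),
                            converged=converged, seed=int(seed))


# ---------------------------------------------------------------------------
# Permutation tests


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray, n: int) -> float:
    r_within = ranks[same_group].mean()
    r_between = ranks[~same_group].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(dist: DistanceMatrix, labels, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Clarke's ANOSIM: R in [-1, 1] and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    computed on midranks of all pairwise dissimilarities; R = 1 means every
    between-group dissimilarity exceeds every within-group one, R ~ 0 means
    no separation.  p = (b + 1)/(n_perm + 1) where b counts permuted R >= observed.
    """
    labels = np.asarray(labels)
    _check_groups(labels, min_size=2)
    n = dist.n
    ranks = stats.rankdata(dist.condensed())
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, same, n)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        same_p = perm[iu] == perm[ju]
        if _anosim_r(ranks, same_p, n) >= r_obs:
            b += 1
    return float(r_obs), (b + 1) / (n_perm + 1)


def _permanova_f(d2: np.ndarray, labels: np.ndarray, iu, ju, n: int) -> float:
    groups, counts = np.unique(labels, return_counts=True)
    ss_total = d2.sum() / n
    ss_within = 0.0
    for g, n_g in zip(groups, counts):
        mask = (labels[iu] == g) & (labels[ju] == g)
        ss_within += d2[mask].sum() / n_g
    a = len(groups)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dist: DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """PERMANOVA pseudo-F from partitioned squared dissimilarities, permutation p."""
    labels = np.asarray(labels)
    _check_groups(labels, min_size=2)
    n = dist.n
    d2 = dist.condensed() ** 2
    iu, ju = np.triu_indices(n, k=1)
    f_obs = _permanova_f(d2, labels, iu, ju, n)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _permanova_f(d2, perm, iu, ju, n) >= f_obs:
            b += 1
    return float(f_obs), (b + 1) / (n_perm + 1)


def _check_groups(labels: np.ndarray, min_size: int) -> None:
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    small = groups[counts < min_size]
    if len(small):
        raise ValueError(f"group(s) {list(small)} have fewer than {min_size} members")


# ---------------------------------------------------------------------------
# Stratigraphically constrained zonation


def _interval_dispersion(p2: np.ndarray, a: int, b: int) -> float:
    """Within-cluster dispersion of samples [a, b): sum of d^2 over pairs / size."""
    if b - a < 2:
        return 0.0
    block = p2[b, b] - p2[a, b] - p2[b, a] + p2[a, a]
    return 0.5 * block / (b - a)


def constrained_zonation(dist: DistanceMatrix) -> Zonation:
    """CONISS-style zonation of a stratigraphically ordered dissimilarity matrix.

    The merge tree joins only adjacent clusters, at each step choosing the
    pair whose union least increases total within-cluster dispersion
    (incremental sum of squared dissimilarities / cluster size).  The
    two-state labeling is the contiguous split minimizing total dispersion,
    found exhaustively over all n - 1 cut points.
    """
    n = dist.n
    if n < 4:
        raise ValueError("zonation needs at least 4 samples")
    d2 = dist.d ** 2
    p2 = np.zeros((n + 1, n + 1))
    p2[1:, 1:] = d2.cumsum(axis=0).cumsum(axis=1)

    # exhaustive optimal two-state contiguous split
    costs = [(_interval_dispersion(p2, 0, c) + _interval_dispersion(p2, c, n), c)
             for c in range(1, n)]
    best_cost, boundary = min(costs)
    labels = np.where(np.arange(n) < boundary, 1, 2)

    # greedy adjacency-constrained agglomeration (dendrogram)
    bounds = list(range(n + 1))  # cluster c = samples [bounds[c], bounds[c+1])
    merges, heights, total = [], [], 0.0
    while len(bounds) > 2:
        best = None
        for c in range(len(bounds) - 2):
            a, m, b = bounds[c], bounds[c + 1], bounds[c + 2]
            cost = (_interval_dispersion(p2, a, b)
                    - _interval_dispersion(p2, a, m)
                    - _interval_dispersion(p2, m, b))
            if best is None or cost < best[0]:
                best = (cost, c)
        cost, c = best
        a, m, b = bounds[c], bounds[c + 1], bounds[c + 2]
        total += cost
        merges.append((a, m, b, cost))
        heights.append(total)
        del bounds[c + 1]
    return Zonation(merges=merges, heights=np.asarray(heights),
                    labels=labels, boundary=int(boundary))


# ---------------------------------------------------------------------------
# KDE bimodality of the state axis


@dataclass
class KDEResult:
    grid: np.ndarray
    density: np.ndarray
    n_modes: int
    mode_locations: np.ndarray
    bandwidth: float
    degenerate: bool = False


def kde_bimodality(values, bandwidth="silverman", grid_size: int = 512) -> KDEResult:
    """Gaussian KDE on a grid spanning the data range +/- 3 bandwidths.

    Modes are strict local maxima of the gridded density.  ``bandwidth`` is
    either the Silverman/Scott rule name or an absolute kernel bandwidth.
    Zero-variance input yields a degenerate spike flagged with one mode.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for a KDE")
    sd = x.std(ddof=1)
    if sd == 0:
        grid = np.linspace(x[0] - 1, x[0] + 1, grid_size)
        density = np.zeros(grid_size)
        density[grid_size // 2] = 1.0
        return KDEResult(grid=grid, density=density, n_modes=1,
                         mode_locations=np.array([x[0]]), bandwidth=0.0,
                         degenerate=True)
    if isinstance(bandwidth, str):
        kde = stats.gaussian_kde(x, bw_method=bandwidth)
    else:
        kde = stats.gaussian_kde(x, bw_method=float(bandwidth) / sd)
    h = kde.factor * sd
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    density = kde(grid)
    interior = (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    modes = np.flatnonzero(interior) + 1
    return KDEResult(grid=grid, density=density, n_modes=int(len(modes)),
                     mode_locations=grid[modes], bandwidth=float(h))
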