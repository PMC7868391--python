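"""Non-parametric cluster-based permutation testing on source-space maps.

The group-level contrast tests, per dipole, each subject's neural activity
index against a paired condition (in the ASSR pipeline: the subject's
whole-brain mean NAI) with a one-sided paired t statistic.  Clusters are
connected components (grid adjacency) of supra-threshold dipoles; the
family-wise error is controlled with the max-cluster-mass permutation
null obtained by random sign flips of the paired differences (equivalent
to exchanging condition labels within subjects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .headmodel import SourceGrid

__all__ = [
    "ClusterResult",
    "adjacency_from_grid",
    "paired_t_map",
    "form_clusters",
    "cluster_permutation_test",
]


@dataclass
class ClusterResult:
    """Outcome of a cluster permutation test.

    ``clusters`` is a list of (member dipole index array, summed-t mass)
    in decreasing mass order; ``p_values`` aligns with it.  ``mask``
    marks dipoles in clusters significant at ``alpha``.
    """

    t_map: np.ndarray
    clusters: list
    p_values: np.ndarray
    mask: np.ndarray
    n_perm: int
    threshold_p: float
    threshold_t: float
    alpha: float
    null_max_mass: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.p_values < self.alpha))


def adjacency_from_grid(grid: SourceGrid | list, connectivity: int = 26
                        ) -> list[np.ndarray]:
    """Neighbour lists for clustering; 26- (default) or 6-neighbourhood."""
    if not isinstance(grid, SourceGrid):
        return [np.asarray(nb, dtype=np.int64) for nb in grid]
    if connectivity == 26:
        return grid.neighbors
    if connectivity == 6:
        out = []
        for p, nb in enumerate(grid.neighbors):
            d = np.abs(grid.lattice[nb] - grid.lattice[p]).sum(axis=1)
            out.append(nb[d == 1])
        return out
    raise ValueError("connectivity must be 6 or 26")


def paired_t_map(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """One-sided paired t statistic per dipole (positive favouring A > B).

    ``A`` and ``B`` are subjects x dipoles and aligned by subject.
    Zero-variance differences yield +/-inf sentinels (with a warning) so
    a genuinely constant positive effect still forms a cluster.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape:
        raise ValueError("condition arrays must have identical shape")
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = A - B
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero & (m != 0)):
        warnings.warn("zero-variance differences: emitting +/-inf t sentinels")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[zero & (m == 0)] = 0.0
    t[zero & (m > 0)] = np.inf
    t[zero & (m < 0)] = -np.inf
    return t


def form_clusters(t_map: np.ndarray, threshold_p: float,
                  adjacency: list | SourceGrid, df: int
                  ) -> tuple[list, float]:
    """Connected supra-threshold clusters of a t map.

    The cluster-forming threshold is the one-sided upper t quantile at
    ``threshold_p`` for ``df`` degrees of freedom.  Returns
    ``([(member indices, mass), ...] sorted by decreasing mass, t*)``.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    adj = adjacency_from_grid(adjacency) if isinstance(adjacency, SourceGrid) \
        else adjacency
    t_star = float(stats.t.ppf(1.0 - threshold_p, df))
    supra = t_map > t_star
    clusters = _components(supra, t_map, adj)
    return clusters, t_star


def _components(supra: np.ndarray, t_map: np.ndarray, adj: list
                ) -> list[tuple[np.ndarray, float]]:
    idx = np.nonzero(supra)[0]
    if idx.size == 0:
        return []
    seen = np.zeros(len(supra), dtype=bool)
    out = []
    for start in idx:
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        stack = [start]
        while stack:
            q = stack.pop()
            for r in adj[q]:
                if supra[r] and not seen[r]:
                    seen[r] = True
                    comp.append(r)
                    stack.append(r)
        comp = np.asarray(sorted(comp), dtype=np.int64)
        out.append((comp, float(t_map[comp].sum())))
    out.sort(key=lambda c: -c[1])
    return out


def cluster_permutation_test(A: np.ndarray, B: np.ndarray,
                             adjacency: list | SourceGrid,
                             n_perm: int = 1000,
                             threshold_p: float = 1e-3,
                             alpha: float = 0.05,
                             rng: np.random.Generator | int | None = None
                             ) -> ClusterResult:
    """Max-cluster-mass permutation test of paired conditions.

    The null exchanges condition labels within subjects — a random sign
    flip of each subject's difference map — and records the largest
    cluster mass per permutation.  Cluster p-values use the +1-corrected
    Monte Carlo estimate p = (1 + #{null >= observed}) / (1 + n_perm);
    clusters with p < alpha are marked significant.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    adj = adjacency_from_grid(adjacency) if isinstance(adjacency, SourceGrid) \
        else adjacency
    n, P = A.shape
    d = A - B
    t_obs = paired_t_map(A, B)
    clusters, t_star = form_clusters(t_obs, threshold_p, adj, n - 1)

    ssq = np.sum(d * d, axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    m = (signs @ d) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.maximum(ssq[None, :] - n * m * m, 0.0) / (n - 1)
        t_null = m / np.sqrt(var / n)
    t_null[~np.isfinite(t_null)] = np.sign(m[~np.isfinite(t_null)]) * np.inf

    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        comps = _components(t_null[i] > t_star, t_null[i], adj)
        if comps:
            null_max[i] = comps[0][1]

    p_values = np.array([
        (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
        for _, mass in clusters
    ])
    mask = np.zeros(P, dtype=bool)
    for (members, _), p in zip(clusters, p_values):
        if p < alpha:
            mask[members] = True
    return ClusterResult(t_map=t_obs, clusters=clusters, p_values=p_values,
                         mask=mask, n_perm=n_perm, threshold_p=threshold_p,
                         threshold_t=t_star, alpha=alpha,
                         null_max_mass=null_max)
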