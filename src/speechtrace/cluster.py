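"""Cluster-based permutation inference over channel x sample maps.

Point-wise F statistics (independent one-way or within-subject
repeated-measures) are thresholded at the parametric F critical value
(alpha = 0.05 by default), suprathreshold points lacking enough
suprathreshold spatial neighbors are pruned (FieldTrip-style
``minnbchan``), connected components over spatial adjacency plus
temporal/spectral contiguity form clusters, and each cluster is scored
by its summed F.  Significance is Monte Carlo: condition labels are
permuted (within subjects for dependent designs, across items for
independent designs), the maximum cluster sum per permutation forms the
null, and p = (1 + #{null >= observed}) / (1 + n_perm).

Spatial adjacency comes from a Delaunay triangulation of the
azimuthal-equidistant projection of the 3-D electrode positions.  For
1-D maps (e.g., stimulus modulation spectra) there is a single "channel"
and clusters are runs of contiguous bins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay

from .montage import azimuthal_projection


@dataclass
class Cluster:
    members: np.ndarray          # (m, 2) array of (channel, sample) indices
    stat: float                  # summed F over members
    p_value: float = np.nan

    def channel_set(self):
        return set(int(c) for c in self.members[:, 0])

    def sample_range(self):
        s = self.members[:, 1]
        return int(s.min()), int(s.max())


@dataclass
class ClusterResult:
    clusters: list               # sorted by descending stat
    stat_map: np.ndarray         # observed F map (channels, samples)
    threshold: float
    null_max: np.ndarray         # null distribution of max cluster sums
    n_permutations: int
    meta: dict = field(default_factory=dict)

    @property
    def significant(self):
        alpha = self.meta.get("alpha", 0.05)
        return [c for c in self.clusters if c.p_value <= alpha]


def adjacency_from_positions(positions: np.ndarray) -> np.ndarray:
    """Boolean channel adjacency from Delaunay-triangulated positions.

    3-D positions are flattened with an azimuthal-equidistant projection
    first; 2-D positions are triangulated directly.  Neighbors share a
    triangle edge.  The matrix is symmetric with a zero diagonal.
    """
    pos = np.asarray(positions, float)
    if pos.ndim != 2 or pos.shape[0] < 3:
        raise ValueError("need at least 3 electrode positions")
    if pos.shape[1] == 3:
        pos = azimuthal_projection(pos)
    if len(np.unique(pos.round(12), axis=0)) < len(pos):
        raise ValueError("duplicate electrode positions")
    tri = Delaunay(pos)
    n = len(pos)
    adj = np.zeros((n, n), bool)
    for simplex in tri.simplices:
        for a, b in itertools.combinations(simplex, 2):
            adj[a, b] = adj[b, a] = True
    return adj


def pointwise_F_indep(groups) -> np.ndarray:
    """One-way between-items ANOVA F at every map point.

    ``groups`` is a sequence of k arrays, each (n_items, *map_shape).
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.shape[0] < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 items each")
    ns = np.array([g.shape[0] for g in groups])
    N = ns.sum()
    means = np.stack([g.mean(axis=0) for g in groups])
    grand = sum(g.sum(axis=0) for g in groups) / N
    ssb = np.sum(ns.reshape(-1, *([1] * (means.ndim - 1)))
                 * (means - grand) ** 2, axis=0)
    ssw = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    if np.all(ssw == 0):
        raise ValueError("zero within-group variance everywhere: F undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
    return np.nan_to_num(F, nan=0.0, posinf=0.0)


def pointwise_F_dep(data) -> np.ndarray:
    """Within-subject one-way (repeated-measures) ANOVA F at every point.

    ``data`` is (n_subjects, k_conditions, *map_shape); the subject is a
    blocking factor, df = (k-1, (k-1)(n-1)).
    """
    y = np.asarray(data, float)
    if y.ndim < 2:
        raise ValueError("expected (subjects, conditions, ...) array")
    if np.isnan(y).any():
        raise ValueError("missing condition cells are not supported")
    n, k = y.shape[:2]
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = y.mean(axis=(0, 1))
    m_s = y.mean(axis=1)                     # (n, ...)
    m_c = y.mean(axis=0)                     # (k, ...)
    ss_cond = n * np.sum((m_c - grand) ** 2, axis=0)
    resid = y - m_s[:, None] - m_c[None] + grand
    ss_err = np.sum(resid ** 2, axis=(0, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return np.nan_to_num(F, nan=0.0, posinf=0.0)


def f_threshold(design: str, k: int, n: int, alpha: float = 0.05) -> float:
    """Parametric F critical value used to form clusters.

    For ``dependent`` designs ``n`` is the number of subjects; for
    ``independent`` it is the total item count across groups.
    """
    if design == "dependent":
        df1, df2 = k - 1, (k - 1) * (n - 1)
    elif design == "independent":
        df1, df2 = k - 1, n - k
    else:
        raise ValueError(f"unknown design {design!r}")
    return float(stats.f.isf(alpha, df1, df2))


def find_clusters(stat_map: np.ndarray, threshold: float,
                  adjacency: np.ndarray | None = None,
                  min_nb_chan: int = 3) -> list[Cluster]:
    """Suprathreshold clusters of a (channels, samples) statistic map.

    Suprathreshold points whose channel has fewer than ``min_nb_chan``
    suprathreshold spatial neighbors at the same sample are pruned
    first (single pass); clusters are then connected components over
    spatial adjacency and sample contiguity, scored by summed statistic.
    Maps with a single channel (or ``adjacency=None``) skip the pruning
    and use pure sample contiguity.
    """
    F = np.atleast_2d(np.asarray(stat_map, float))
    n_ch, n_pt = F.shape
    mask = F > threshold
    if adjacency is not None and n_ch > 1 and min_nb_chan > 0:
        nb_count = adjacency.astype(int) @ mask.astype(int)
        mask &= nb_count >= min_nb_chan
    if not mask.any():
        return []
    idx = np.flatnonzero(mask.ravel())
    node_of = -np.ones(n_ch * n_pt, int)
    node_of[idx] = np.arange(len(idx))
    rows, cols = [], []
    ch_i, pt_i = np.unravel_index(idx, (n_ch, n_pt))
    # temporal/spectral contiguity: same channel, adjacent samples
    right = idx + 1
    ok = (pt_i < n_pt - 1) & (node_of[np.minimum(right, n_ch * n_pt - 1)] >= 0)
    rows.extend(node_of[idx[ok]])
    cols.extend(node_of[right[ok]])
    # spatial adjacency: adjacent channels, same sample
    if adjacency is not None and n_ch > 1:
        a_idx, b_idx = np.nonzero(np.triu(adjacency, 1))
        for a, b in zip(a_idx, b_idx):
            both = mask[a] & mask[b]
            pts = np.flatnonzero(both)
            rows.extend(node_of[a * n_pt + pts])
            cols.extend(node_of[b * n_pt + pts])
    g = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(g, directed=False)
    clusters = []
    for c in range(n_comp):
        members_flat = idx[labels == c]
        ch, pt = np.unravel_index(members_flat, (n_ch, n_pt))
        members = np.column_stack([ch, pt])
        clusters.append(Cluster(members=members,
                                stat=float(F[ch, pt].sum())))
    clusters.sort(key=lambda c: -c.stat)
    return clusters


def _max_cluster_sum(F, threshold, adjacency, min_nb_chan) -> float:
    cl = find_clusters(F, threshold, adjacency, min_nb_chan)
    return cl[0].stat if cl else 0.0


def _dep_perm_indices(rng, n_subj, k):
    """One within-subject label permutation: (n_subj, k) index array."""
    return np.argsort(rng.random((n_subj, k)), axis=1)


def permutation_test(data, design: str, adjacency: np.ndarray | None = None,
                     n_perm: int = 5000, seed: int | None = None,
                     alpha: float = 0.05, min_nb_chan: int = 3,
                     threshold: float | None = None,
                     exhaustive: bool = False) -> ClusterResult:
    """Cluster-based permutation test with the maxsum statistic.

    ``design="dependent"``: ``data`` is (n_subjects, k, channels,
    samples) and condition labels are permuted within each subject.
    ``design="independent"``: ``data`` is a sequence of k arrays
    (n_items, channels, samples) and item labels are permuted across
    groups.  ``exhaustive=True`` (dependent only, tiny designs)
    enumerates all (k!)^n within-subject relabelings instead of Monte
    Carlo sampling; p is then the exact proportion of relabelings
    (including the identity) whose max cluster sum reaches the observed.
    """
    if design == "dependent":
        y = np.asarray(data, float)
        if y.ndim == 3:
            y = y[:, :, None, :]
        n_subj, k = y.shape[:2]
        n_for_df = n_subj
        F_obs = pointwise_F_dep(y)
    elif design == "independent":
        groups = [np.atleast_3d(np.asarray(g, float)) for g in data]
        k = len(groups)
        ns = [g.shape[0] for g in groups]
        n_for_df = sum(ns)
        F_obs = pointwise_F_indep(groups)
        pooled = np.concatenate(groups, axis=0)
        edges = np.cumsum([0] + ns)
    else:
        raise ValueError(f"unknown design {design!r}")
    if threshold is None:
        threshold = f_threshold(design, k, n_for_df, alpha)
    F_obs = np.atleast_2d(F_obs)
    observed = find_clusters(F_obs, threshold, adjacency, min_nb_chan)

    if exhaustive:
        if design != "dependent":
            raise ValueError("exhaustive enumeration requires a dependent design")
        perms = list(itertools.permutations(range(k)))
        total = len(perms) ** n_subj
        if total > 200_000:
            raise ValueError(f"{total} relabelings: too many to enumerate")
        null = np.empty(total)
        for i, combo in enumerate(itertools.product(perms, repeat=n_subj)):
            yp = np.stack([y[s, list(combo[s])] for s in range(n_subj)])
            null[i] = _max_cluster_sum(pointwise_F_dep(yp), threshold,
                                       adjacency, min_nb_chan)
        for c in observed:
            c.p_value = float(np.mean(null >= c.stat - 1e-12))
        return ClusterResult(clusters=observed, stat_map=F_obs,
                             threshold=threshold, null_max=null,
                             n_permutations=total,
                             meta=dict(design=design, alpha=alpha,
                                       exhaustive=True))

    if seed is None:
        raise ValueError("Monte Carlo permutation requires a seed")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p values will be coarse")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        if design == "dependent":
            idx = _dep_perm_indices(rng, n_subj, k)
            yp = np.take_along_axis(
                y, idx.reshape(n_subj, k, *([1] * (y.ndim - 2))), axis=1)
            Fp = pointwise_F_dep(yp)
        else:
            order = rng.permutation(n_for_df)
            regrouped = [pooled[order[edges[i]:edges[i + 1]]]
                         for i in range(k)]
            Fp = pointwise_F_indep(regrouped)
        null[p] = _max_cluster_sum(np.atleast_2d(Fp), threshold,
                                   adjacency, min_nb_chan)
    for c in observed:
        c.p_value = float((1 + np.sum(null >= c.stat - 1e-12))
                          / (1 + n_perm))
    return ClusterResult(clusters=observed, stat_map=F_obs,
                         threshold=threshold, null_max=null,
                         n_permutations=n_perm,
                         meta=dict(design=design, alpha=alpha, seed=seed))
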