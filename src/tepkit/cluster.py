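"""Cluster-based permutation statistics over channels/parcels x time.

Mass-univariate dependent-samples t (sign-flip null) or repeated-measures
F (within-subject label-permutation null), thresholded pointwise and
clustered under combined spatial (neighbor graph) + temporal (consecutive
samples) adjacency. Cluster mass is the sum of the statistic over members;
significance comes from the permutation distribution of the maximum
cluster mass, so the family-wise error over the whole spatiotemporal grid
is controlled.

A minimum-neighbor rule (used for parcel-space "channels") prunes
suprathreshold points that have fewer than ``min_neighbors`` suprathreshold
spatial neighbors at the same sample before clustering.

The two-stage procedure first finds significant time windows on the full
grid, then averages within each window and runs a spatial-only cluster
test (with pairwise post-hoc tests after an ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NeighborGraph",
    "ClusterParams",
    "Cluster",
    "ClusterTestResult",
    "TwoStageResult",
    "build_neighbors",
    "cluster_ttest",
    "cluster_anova",
    "two_stage_test",
]


@dataclass
class NeighborGraph:
    """Symmetric adjacency over sensors or parcels.

    ``min_neighbors`` is the number of simultaneously suprathreshold
    spatial neighbors a point needs to enter a cluster (0 for sensors,
    typically 3 for parcel spaces).
    """

    labels: list[str]
    adjacency: list[set[int]]
    min_neighbors: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.adjacency):
            raise ValueError("labels/adjacency length mismatch")
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise ValueError("no self-edges allowed")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def isolated_nodes(self) -> list[str]:
        return [self.labels[i] for i, nb in enumerate(self.adjacency) if not nb]


@dataclass(frozen=True)
class ClusterParams:
    """Test configuration.

    ``cluster_alpha`` is the pointwise cluster-forming threshold
    probability (two-sided for t, upper-tail for F) on the parametric
    reference distribution; ``alpha`` the cluster-level significance
    threshold; ``cluster_stat`` one of 'sum' (mass), 'size', 'max'.
    """

    test_window_ms: tuple[float, float] = (20.0, 300.0)
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    cluster_stat: str = "sum"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.cluster_stat not in ("sum", "size", "max"):
            raise ValueError("cluster_stat must be 'sum', 'size' or 'max'")


@dataclass
class Cluster:
    members: list[tuple[int, int]]  # (node, sample) pairs
    mass: float  # summary statistic per cluster_stat (signed for t)
    sign: int  # +1 / -1 for t clusters, +1 for F
    p_value: float = np.nan

    @property
    def nodes(self) -> set[int]:
        return {n for n, _ in self.members}

    @property
    def sample_range(self) -> tuple[int, int]:
        ss = [s for _, s in self.members]
        return min(ss), max(ss)


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    stat_map: np.ndarray  # nodes x samples
    threshold: float
    times: np.ndarray | None
    n_permutations: int
    null_max: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def significant_windows(self, alpha: float = 0.05) -> list[tuple[float, float]]:
        """Merged time intervals (ms) spanned by significant clusters."""
        if self.times is None:
            return []
        spans = []
        for c in self.significant(alpha):
            s0, s1 = c.sample_range
            spans.append((float(self.times[s0]), float(self.times[s1])))
        spans.sort()
        merged: list[tuple[float, float]] = []
        for lo, hi in spans:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged


# --------------------------------------------------------------------------
# graph construction
# --------------------------------------------------------------------------

def build_neighbors(
    labels: list[str],
    positions: np.ndarray | None = None,
    adjacency: list[set[int]] | None = None,
    rule: str = "distance",
    distance_threshold: float | None = None,
    k: int | None = None,
    min_neighbors: int = 0,
) -> NeighborGraph:
    """Build a symmetric neighbor graph from positions or a given adjacency.

    ``rule='distance'`` links nodes closer than ``distance_threshold``;
    ``rule='knn'`` links each node to its ``k`` nearest and symmetrizes.
    Isolated nodes are permitted (query with ``isolated_nodes``).
    """
    if not labels:
        raise ValueError("empty layout")
    if adjacency is not None:
        return NeighborGraph(list(labels), [set(s) for s in adjacency], min_neighbors)
    if positions is None:
        raise ValueError("need positions or adjacency")
    pos = np.asarray(positions, dtype=float)
    if len(labels) < 2:
        raise ValueError("need at least 2 nodes")
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    adj: list[set[int]] = [set() for _ in labels]
    if rule == "distance":
        if distance_threshold is None:
            raise ValueError("distance rule needs distance_threshold")
        for i, j in zip(*np.where(d < distance_threshold)):
            adj[i].add(int(j))
    elif rule == "knn":
        if k is None:
            raise ValueError("knn rule needs k")
        for i in range(len(labels)):
            for j in np.argsort(d[i])[:k]:
                adj[i].add(int(j))
                adj[int(j)].add(i)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return NeighborGraph(list(labels), adj, min_neighbors)


# --------------------------------------------------------------------------
# clustering core
# --------------------------------------------------------------------------

def _prune_min_neighbors(mask: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Drop suprathreshold points with < min_neighbors suprathreshold
    spatial neighbors at the same sample (applied once, not iterated)."""
    if graph.min_neighbors <= 0:
        return mask
    count = np.zeros_like(mask, dtype=int)
    for i, nbrs in enumerate(graph.adjacency):
        for j in nbrs:
            count[i] += mask[j]
    return mask & (count >= graph.min_neighbors)


def _connected_clusters(
    mask: np.ndarray, stat: np.ndarray, graph: NeighborGraph, cluster_stat: str
) -> list[tuple[list[tuple[int, int]], float]]:
    """Connected components of the mask under spatial+temporal adjacency."""
    n_nodes, n_samp = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    out = []
    idx_nodes, idx_samps = np.where(mask)
    for start_n, start_s in zip(idx_nodes, idx_samps):
        if seen[start_n, start_s]:
            continue
        stack = [(int(start_n), int(start_s))]
        seen[start_n, start_s] = True
        members: list[tuple[int, int]] = []
        while stack:
            i, s = stack.pop()
            members.append((i, s))
            for j in graph.adjacency[i]:
                if mask[j, s] and not seen[j, s]:
                    seen[j, s] = True
                    stack.append((j, s))
            for s2 in (s - 1, s + 1):
                if 0 <= s2 < n_samp and mask[i, s2] and not seen[i, s2]:
                    seen[i, s2] = True
                    stack.append((i, s2))
        vals = stat[tuple(np.array(members).T)]
        if cluster_stat == "sum":
            mass = float(vals.sum())
        elif cluster_stat == "size":
            mass = float(np.sign(vals.sum()) * len(members))
        else:  # max
            mass = float(vals[np.argmax(np.abs(vals))])
        out.append((members, mass))
    return out


def _clusters_from_map(
    stat: np.ndarray,
    threshold: float,
    graph: NeighborGraph,
    cluster_stat: str,
    two_sided: bool,
) -> list[Cluster]:
    clusters: list[Cluster] = []
    masks = [(stat > threshold, 1)]
    if two_sided:
        masks.append((stat < -threshold, -1))
    for mask, sign in masks:
        mask = _prune_min_neighbors(mask, graph)
        for members, mass in _connected_clusters(mask, stat, graph, cluster_stat):
            clusters.append(Cluster(members=members, mass=mass, sign=sign))
    return clusters


def _max_cluster_mass(
    stat: np.ndarray,
    threshold: float,
    graph: NeighborGraph,
    cluster_stat: str,
    two_sided: bool,
) -> float:
    best = 0.0
    for c in _clusters_from_map(stat, threshold, graph, cluster_stat, two_sided):
        best = max(best, abs(c.mass))
    return best


# --------------------------------------------------------------------------
# statistic maps
# --------------------------------------------------------------------------

def _paired_t_maps(diff_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for sign-flip configurations.

    diff_flat: (n_subjects, P); signs: (B, n_subjects) of +/-1.
    Returns (B, P). Points with zero variance get t = 0.
    """
    n = diff_flat.shape[0]
    m = signs @ diff_flat / n
    sq = np.mean(diff_flat**2, axis=0)[None, :]
    var = (sq - m**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0
    return t


def _rm_f_maps(x: np.ndarray) -> np.ndarray:
    """Repeated-measures F maps.

    x: (..., k, n, P) -> F: (..., P); zero-variance points get F = 0.
    """
    k, n = x.shape[-3], x.shape[-2]
    gm = x.mean(axis=(-3, -2), keepdims=True)
    cm = x.mean(axis=-2, keepdims=True)  # condition means
    sm = x.mean(axis=-3, keepdims=True)  # subject means
    ss_cond = n * ((cm - gm) ** 2).sum(axis=(-3, -2))
    resid = x - cm - sm + gm
    ss_err = (resid**2).sum(axis=(-3, -2))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    f = np.asarray(f)
    f[~np.isfinite(f)] = 0.0
    # guard against 0/0 float residue when conditions are (near-)identical:
    # a between-condition SS that is negligible against the total variance
    # cannot carry a real effect
    total = ((x - gm) ** 2).sum(axis=(-3, -2))
    f[ss_cond <= 1e-12 * np.maximum(total, np.finfo(float).tiny)] = 0.0
    return f


def _restrict(
    data: np.ndarray, times: np.ndarray | None, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray | None]:
    if times is None:
        return data, None
    m = (times >= window[0]) & (times < window[1])
    if not m.any():
        raise ValueError(f"test window {window} ms outside the data grid")
    return data[..., m], times[m]


def _assign_pvalues(clusters: list[Cluster], null_max: np.ndarray) -> None:
    p_tot = null_max.size
    for c in clusters:
        b = int(np.sum(null_max >= abs(c.mass)))
        c.p_value = (b + 1) / (p_tot + 1)


# --------------------------------------------------------------------------
# tests
# --------------------------------------------------------------------------

def cluster_ttest(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    graph: NeighborGraph,
    params: ClusterParams | None = None,
    seed: int | None = None,
    times: np.ndarray | None = None,
    _batch: int = 200,
) -> ClusterTestResult:
    """Dependent-samples cluster t-test between two paired conditions.

    ``cond_a``/``cond_b``: (n_subjects, n_nodes, n_samples), subject-paired.
    The null is built by randomly sign-flipping each subject's difference
    map and taking the maximum absolute cluster mass per permutation.
    """
    params = params or ClusterParams()
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("paired conditions must have identical shapes")
    if cond_a.ndim != 3 or cond_a.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_nodes, n_samples) arrays")
    if cond_a.shape[1] != graph.n_nodes:
        raise ValueError("node dimension does not match the neighbor graph")
    diff, times_r = _restrict(cond_a - cond_b, times, params.test_window_ms)
    n, n_nodes, n_samp = diff.shape
    flat = diff.reshape(n, -1)
    threshold = float(stats.t.ppf(1 - params.cluster_alpha / 2, n - 1))

    t_obs = _paired_t_maps(flat, np.ones((1, n)))[0].reshape(n_nodes, n_samp)
    clusters = _clusters_from_map(t_obs, threshold, graph, params.cluster_stat, True)

    rng = np.random.default_rng(seed)
    null_max = np.empty(params.n_permutations)
    done = 0
    while done < params.n_permutations:
        b = min(_batch, params.n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(b, n))
        t_perm = _paired_t_maps(flat, signs).reshape(b, n_nodes, n_samp)
        for i in range(b):
            null_max[done + i] = _max_cluster_mass(
                t_perm[i], threshold, graph, params.cluster_stat, True
            )
        done += b
    _assign_pvalues(clusters, null_max)
    return ClusterTestResult(
        clusters=clusters,
        stat_map=t_obs,
        threshold=threshold,
        times=times_r,
        n_permutations=params.n_permutations,
        null_max=null_max,
    )


def cluster_anova(
    conds: list[np.ndarray],
    graph: NeighborGraph,
    params: ClusterParams | None = None,
    seed: int | None = None,
    times: np.ndarray | None = None,
    _batch: int = 100,
) -> ClusterTestResult:
    """Repeated-measures cluster F-test across k paired conditions.

    The null permutes condition labels independently within each subject
    and takes the maximum cluster mass of the resulting F maps.
    """
    params = params or ClusterParams()
    arrs = [np.asarray(c, dtype=float) for c in conds]
    if len(arrs) < 2:
        raise ValueError("need at least 2 conditions")
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all conditions must share (subjects, nodes, samples)")
    x = np.stack(arrs)  # (k, n, nodes, samples)
    k, n = x.shape[0], x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if x.shape[2] != graph.n_nodes:
        raise ValueError("node dimension does not match the neighbor graph")
    x, times_r = _restrict(x, times, params.test_window_ms)
    n_nodes, n_samp = x.shape[2], x.shape[3]
    xf = x.reshape(k, n, -1)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    threshold = float(stats.f.ppf(1 - params.cluster_alpha, df1, df2))

    f_obs = _rm_f_maps(xf).reshape(n_nodes, n_samp)
    clusters = _clusters_from_map(f_obs, threshold, graph, params.cluster_stat, False)

    rng = np.random.default_rng(seed)
    null_max = np.empty(params.n_permutations)
    done = 0
    while done < params.n_permutations:
        b = min(_batch, params.n_permutations - done)
        idx = np.empty((b, k, n), dtype=int)
        for bi in range(b):
            for si in range(n):
                idx[bi, :, si] = rng.permutation(k)
        xp = xf[idx, np.arange(n)[None, None, :], :]  # (b, k, n, P)
        f_perm = _rm_f_maps(xp).reshape(b, n_nodes, n_samp)
        for i in range(b):
            null_max[done + i] = _max_cluster_mass(
                f_perm[i], threshold, graph, params.cluster_stat, False
            )
        done += b
    _assign_pvalues(clusters, null_max)
    return ClusterTestResult(
        clusters=clusters,
        stat_map=f_obs,
        threshold=threshold,
        times=times_r,
        n_permutations=params.n_permutations,
        null_max=null_max,
    )


@dataclass
class TwoStageResult:
    stage1: ClusterTestResult
    windows: list[tuple[float, float]]
    # one spatial-only result per stage-1 window; for >2 conditions also
    # pairwise post-hoc t results keyed by (i, j)
    stage2: list[ClusterTestResult]
    posthoc: list[dict[tuple[int, int], ClusterTestResult]]


def _window_average(
    data: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> np.ndarray:
    m = (times >= window[0]) & (times <= window[1])
    return data[..., m].mean(axis=-1, keepdims=True)


def two_stage_test(
    conds: list[np.ndarray],
    graph: NeighborGraph,
    params: ClusterParams | None = None,
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> TwoStageResult:
    """Window-then-channel cluster procedure.

    Stage 1 runs the full spatiotemporal test (t for 2 conditions, ANOVA
    for more) and extracts the significant time windows. Stage 2 averages
    each subject's maps over each window and reruns a spatial-only cluster
    test restricted to those averages; after a significant ANOVA, pairwise
    post-hoc t-tests run within each window. No stage-1 windows is a valid
    empty outcome, not an error.
    """
    params = params or ClusterParams()
    if times is None:
        raise ValueError("two_stage_test needs the time grid")
    is_pair = len(conds) == 2
    if is_pair:
        stage1 = cluster_ttest(conds[0], conds[1], graph, params, seed, times)
    else:
        stage1 = cluster_anova(conds, graph, params, seed, times)
    windows = stage1.significant_windows(params.alpha)

    spatial_params = ClusterParams(
        test_window_ms=(-np.inf, np.inf),
        alpha=params.alpha,
        cluster_alpha=params.cluster_alpha,
        n_permutations=params.n_permutations,
        cluster_stat=params.cluster_stat,
    )
    stage2: list[ClusterTestResult] = []
    posthoc: list[dict[tuple[int, int], ClusterTestResult]] = []
    for wi, window in enumerate(windows):
        avgs = [_window_average(c, times, window) for c in conds]
        wseed = None if seed is None else seed + 1000 * (wi + 1)
        if is_pair:
            stage2.append(
                cluster_ttest(avgs[0], avgs[1], graph, spatial_params, wseed)
            )
            posthoc.append({})
        else:
            stage2.append(cluster_anova(avgs, graph, spatial_params, wseed))
            pairs: dict[tuple[int, int], ClusterTestResult] = {}
            if stage2[-1].significant(params.alpha):
                for i in range(len(conds)):
                    for j in range(i + 1, len(conds)):
                        pseed = None if wseed is None else wseed + 10 * i + j
                        pairs[(i, j)] = cluster_ttest(
                            avgs[i], avgs[j], graph, spatial_params, pseed
                        )
            posthoc.append(pairs)
    return TwoStageResult(stage1=stage1, windows=windows, stage2=stage2, posthoc=posthoc)
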