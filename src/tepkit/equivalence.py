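"""Bootstrap ROPE equivalence testing across conditions.

Detecting "no difference" needs more than a non-significant test; here
equivalence is demonstrated when the bootstrap distribution of the mean
difference between two conditions lies almost entirely inside a Region of
Practical Equivalence (ROPE) of +/- d_threshold x pooled SD (Cohen's d
scale). Subjects are resampled with replacement jointly across conditions
(preserving the repeated-measures pairing); per resample, the pairwise
mean differences and the pairwise-pooled SD are computed, and the coverage
is the fraction of resamples whose difference falls inside its ROPE.
Equivalence is declared for a pair iff coverage strictly exceeds the
coverage threshold (default 97.5%). This generalizes the parametric TOST
procedure to non-parametric distributions and multiple groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "EquivParams",
    "EquivalenceResult",
    "TimecourseEquivalence",
    "is_equivalent",
    "window_amplitudes",
    "bootstrap_equivalence",
    "timecourse_equivalence",
]

DEFAULT_WINDOWS_MS: tuple[tuple[float, float], ...] = (
    (30.0, 50.0),
    (50.0, 80.0),
    (80.0, 120.0),
    (120.0, 200.0),
)


@dataclass(frozen=True)
class EquivParams:
    windows_ms: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_MS
    n_boot: int = 10_000
    d_threshold: float = 0.4  # Cohen's d defining the ROPE half-width
    coverage_threshold: float = 0.975
    timecourse_window_ms: tuple[float, float] = (20.0, 300.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold < 1:
            raise ValueError("coverage_threshold must be in (0, 1)")
        if self.d_threshold <= 0:
            raise ValueError("d_threshold must be positive")
        wins = sorted(self.windows_ms)
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            if b0 < a1:
                raise ValueError("windows must be non-overlapping")


def is_equivalent(coverage: float, threshold: float = 0.975) -> bool:
    """Strict decision rule: coverage must exceed the threshold."""
    return coverage > threshold


@dataclass
class EquivalenceResult:
    pairs: list[tuple[int, int]]
    mean_diff: np.ndarray  # observed mean difference per pair
    boot_quantiles: np.ndarray  # (n_pairs, 3): 2.5 / 50 / 97.5 percentiles
    pooled_sd: np.ndarray  # mean across resamples, per pair
    rope_bounds: np.ndarray  # (n_pairs, 2), symmetric about 0
    coverage: np.ndarray  # per pair, in [0, 1]
    decisions: list[bool]  # equivalent iff coverage > threshold
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def overall_p(self) -> float:
        """Worst (largest) per-pair p, the conservative summary."""
        return float(self.p_values.max()) if self.p_values.size else np.nan

    @property
    def all_equivalent(self) -> bool:
        return all(self.decisions)


def window_amplitudes(
    cond_maps: list[np.ndarray],
    times: np.ndarray,
    windows_ms: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS_MS,
    nodes: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Average amplitude per subject x condition x window.

    ``cond_maps``: one (n_subjects, n_nodes, n_samples) array per
    condition, subject-aligned. ``nodes`` selects the channels/parcels to
    pool (all by default); pooling happens within subject before any group
    statistic. Windows are [lo, hi) on the sample grid.
    """
    arrs = [np.asarray(c, dtype=float) for c in cond_maps]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("all conditions must share (subjects, nodes, samples)")
    sel = np.arange(arrs[0].shape[1]) if nodes is None else np.asarray(nodes)
    out = np.empty((arrs[0].shape[0], len(arrs), len(windows_ms)))
    for wi, (lo, hi) in enumerate(windows_ms):
        m = (times >= lo) & (times < hi)
        if not m.any():
            raise ValueError(f"window [{lo}, {hi}) ms outside the data grid")
        for ci, a in enumerate(arrs):
            out[:, ci, wi] = a[:, sel][:, :, m].mean(axis=(1, 2))
    return out


def bootstrap_equivalence(
    table: np.ndarray,
    params: EquivParams | None = None,
    seed: int | None = None,
) -> EquivalenceResult:
    """ROPE equivalence test on a subjects x conditions amplitude table.

    For each of ``n_boot`` resamples of subjects (with replacement, the
    same resampled subjects contributing all conditions), the pairwise
    mean differences and the pairwise-pooled SD
    (sqrt of the mean of the two conditions' variances) are computed; a
    resample counts as inside the ROPE when |difference| <= d_threshold x
    its pooled SD. Coverage is averaged over resamples and compared
    strictly against the coverage threshold. Per-pair p = 1 - coverage.
    """
    params = params or EquivParams()
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, conditions >= 2) table")
    n, k = table.shape
    pairs = list(combinations(range(k), 2))
    obs_sd = table.std(axis=0, ddof=1)
    for i, j in pairs:
        if np.sqrt((obs_sd[i] ** 2 + obs_sd[j] ** 2) / 2) == 0:
            raise ValueError(
                f"degenerate data: zero pooled SD for condition pair ({i}, {j})"
            )

    rng = np.random.default_rng(params.seed if seed is None else seed)
    idx = rng.integers(0, n, size=(params.n_boot, n))
    sampled = table[idx]  # (n_boot, n, k)
    means = sampled.mean(axis=1)
    sds = sampled.std(axis=1, ddof=1)

    n_pairs = len(pairs)
    mean_diff = np.empty(n_pairs)
    quants = np.empty((n_pairs, 3))
    pooled_mean = np.empty(n_pairs)
    rope = np.empty((n_pairs, 2))
    coverage = np.empty(n_pairs)
    for pi, (i, j) in enumerate(pairs):
        diffs = means[:, i] - means[:, j]
        pooled = np.sqrt((sds[:, i] ** 2 + sds[:, j] ** 2) / 2.0)
        inside = np.abs(diffs) <= params.d_threshold * pooled
        coverage[pi] = inside.mean()
        mean_diff[pi] = table[:, i].mean() - table[:, j].mean()
        quants[pi] = np.percentile(diffs, [2.5, 50, 97.5])
        pooled_mean[pi] = pooled.mean()
        half = params.d_threshold * pooled_mean[pi]
        rope[pi] = (-half, half)
    decisions = [is_equivalent(c, params.coverage_threshold) for c in coverage]
    return EquivalenceResult(
        pairs=pairs,
        mean_diff=mean_diff,
        boot_quantiles=quants,
        pooled_sd=pooled_mean,
        rope_bounds=rope,
        coverage=coverage,
        decisions=decisions,
        p_values=1.0 - coverage,
    )


@dataclass
class TimecourseEquivalence:
    times: np.ndarray  # ms, the tested samples
    pairs: list[tuple[int, int]]
    coverage: np.ndarray  # (n_pairs, n_samples)
    decisions: np.ndarray  # (n_pairs, n_samples) bool
    intervals: list[tuple[float, float]]  # all-pairs-equivalent runs, ms


def timecourse_equivalence(
    timecourses: np.ndarray,
    times: np.ndarray,
    params: EquivParams | None = None,
    seed: int | None = None,
    _chunk: int = 500,
) -> TimecourseEquivalence:
    """Sample-wise ROPE equivalence over a region-of-interest time-course.

    ``timecourses``: (n_subjects, n_conditions, n_samples) subject-aligned
    signals (already averaged over the region of interest). The bootstrap
    draws one set of subject resamples per iteration and applies it to
    every sample, then the windowed decision rule runs per sample;
    contiguous runs where *all* pairwise decisions are equivalent are
    reported as intervals on the sample grid.
    """
    params = params or EquivParams()
    x = np.asarray(timecourses, dtype=float)
    if x.ndim != 3:
        raise ValueError("need (subjects, conditions, samples)")
    n, k, _ = x.shape
    m = (times >= params.timecourse_window_ms[0]) & (
        times < params.timecourse_window_ms[1]
    )
    if not m.any():
        raise ValueError("time-course window outside the data grid")
    x = x[:, :, m]
    t_sel = times[m]
    s = x.shape[2]
    pairs = list(combinations(range(k), 2))

    rng = np.random.default_rng(params.seed if seed is None else seed)
    inside_counts = np.zeros((len(pairs), s))
    done = 0
    while done < params.n_boot:
        b = min(_chunk, params.n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        sampled = x[idx]  # (b, n, k, s)
        means = sampled.mean(axis=1)  # (b, k, s)
        sds = sampled.std(axis=1, ddof=1)
        for pi, (i, j) in enumerate(pairs):
            diffs = means[:, i] - means[:, j]
            pooled = np.sqrt((sds[:, i] ** 2 + sds[:, j] ** 2) / 2.0)
            inside_counts[pi] += (
                np.abs(diffs) <= params.d_threshold * pooled
            ).sum(axis=0)
        done += b

    coverage = inside_counts / params.n_boot
    decisions = coverage > params.coverage_threshold
    all_eq = decisions.all(axis=0)
    intervals: list[tuple[float, float]] = []
    start = None
    for si in range(s):
        if all_eq[si] and start is None:
            start = si
        elif not all_eq[si] and start is not None:
            intervals.append((float(t_sel[start]), float(t_sel[si - 1])))
            start = None
    if start is not None:
        intervals.append((float(t_sel[start]), float(t_sel[-1])))
    return TimecourseEquivalence(
        times=t_sel, pairs=pairs, coverage=coverage,
        decisions=decisions, intervals=intervals,
    )
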