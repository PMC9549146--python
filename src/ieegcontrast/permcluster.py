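"""Cluster-level permutation test for condition contrasts in gamma power traces.

For two groups of single-trial traces (angry vs happy), a pointwise
two-sample t statistic is thresholded at the two-sided quantile implied by
the cluster-forming p value; contiguous supra-threshold runs form clusters
(positive and negative deflections separately) whose statistic is the
cluster mass, the sum of t inside the run. The null distribution is the
maximum absolute cluster mass over random relabelings of the trials, and the
Monte-Carlo p value uses the +1 finite-permutation correction so p is never
zero. A contact or structure shows a significant contrast when at least one
cluster has p below the cluster significance level.

Structure-level tests pool (concatenate) the trials of every contact
assigned to the same (structure, hemisphere), mirroring group-level
aggregation across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectral import GammaPowerTraces


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    cluster_forming_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 1 and 0 < self.cluster_forming_p < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class Cluster:
    start: int          # first time index (inclusive)
    stop: int           # last time index (exclusive)
    mass: float         # sum of pointwise t inside the cluster
    p_value: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    threshold: float
    n_permutations: int
    null_max_mass: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        return any(c.significant for c in self.clusters)

    def cluster_windows(self, times: np.ndarray) -> list[tuple[float, float]]:
        return [(float(times[c.start]), float(times[c.stop - 1])) for c in self.clusters]


def _pooled_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Two-sample pooled-variance t from per-group sums and sums of squares."""
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    var_a = (sumsq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (sumsq_b - n_b * mean_b**2) / (n_b - 1)
    sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return np.where(denom > 0, t, 0.0)


def _clusters_and_masses(t_row: np.ndarray, threshold: float) -> tuple[list[tuple[int, int]], list[float]]:
    """Contiguous supra-threshold runs; positive and negative handled separately."""
    spans: list[tuple[int, int]] = []
    masses: list[float] = []
    for sign in (1.0, -1.0):
        mask = (sign * t_row) > threshold
        if not mask.any():
            continue
        padded = np.r_[False, mask, False]
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            spans.append((int(start), int(stop)))
            masses.append(float(t_row[start:stop].sum()))
    order = np.argsort([s[0] for s in spans])
    return [spans[i] for i in order], [masses[i] for i in order]


def cluster_permutation_test(traces_a: np.ndarray, traces_b: np.ndarray,
                             config: PermutationConfig | None = None) -> ClusterResult:
    """Nonparametric cluster-level permutation test between two trial groups.

    ``traces_a``/``traces_b`` are [trials x timepoints] on a common axis.
    """
    config = config or PermutationConfig()
    a = np.atleast_2d(np.asarray(traces_a, float))
    b = np.atleast_2d(np.asarray(traces_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"time axes differ: {a.shape[1]} vs {b.shape[1]} samples")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("each condition needs at least 2 trials")

    df = n_a + n_b - 2
    threshold = float(stats.t.ppf(1.0 - config.cluster_forming_p / 2.0, df))

    # canonical row order makes the Monte-Carlo null (hence p) invariant to
    # the order trials are supplied in
    x = np.vstack([a, b])                       # [n x T]
    x = x[np.lexsort(x.T[::-1])]
    xsq = x**2
    tot_sum, tot_sumsq = x.sum(0), xsq.sum(0)

    t_obs = _pooled_t(a.sum(0), (a**2).sum(0), n_a, b.sum(0), (b**2).sum(0), n_b)
    spans, masses = _clusters_and_masses(t_obs, threshold)

    # Null: max |cluster mass| under random relabelings, vectorized over
    # permutations via 0/1 selection matrices.
    rng = np.random.default_rng(config.seed)
    n = n_a + n_b
    sel = np.zeros((config.n_permutations, n), float)
    for i in range(config.n_permutations):
        sel[i, rng.choice(n, size=n_a, replace=False)] = 1.0
    sum_a = sel @ x
    sumsq_a = sel @ xsq
    t_null = _pooled_t(sum_a, sumsq_a, n_a, tot_sum - sum_a, tot_sumsq - sumsq_a, n_b)

    null_max = np.zeros(config.n_permutations)
    for i in range(config.n_permutations):
        _, m = _clusters_and_masses(t_null[i], threshold)
        if m:
            null_max[i] = max(abs(v) for v in m)

    clusters = []
    for (start, stop), mass in zip(spans, masses):
        p = (1.0 + float(np.sum(null_max >= abs(mass)))) / (1.0 + config.n_permutations)
        clusters.append(Cluster(start, stop, mass, p, p < config.cluster_alpha))
    return ClusterResult(clusters=clusters, t_values=t_obs, threshold=threshold,
                         n_permutations=config.n_permutations, null_max_mass=null_max)


def structure_pooled_test(gpts_by_contact: list[GammaPowerTraces],
                          config: PermutationConfig | None = None) -> ClusterResult:
    """Pool trials from all contacts of one (structure, hemisphere), then test.

    Trials from different contacts (and subjects) are simply concatenated
    into one angry and one happy group; every trial weighs equally.
    """
    if not gpts_by_contact:
        raise ValueError("no contacts to pool")
    keys = {(g.contact.label, g.contact.hemisphere) for g in gpts_by_contact}
    if len(keys) > 1:
        raise ValueError(f"contacts span multiple structures: {sorted(keys)}")
    n_t = {len(g.times) for g in gpts_by_contact}
    if len(n_t) > 1:
        raise ValueError("contacts must share one time axis")
    a = np.vstack([g.split_conditions()[0] for g in gpts_by_contact])
    b = np.vstack([g.split_conditions()[1] for g in gpts_by_contact])
    return cluster_permutation_test(a, b, config)
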