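"""Whole time–scalp nonparametric statistics with cluster-based permutation.

At every (electrode, time-bin) site a rank test compares conditions
(Friedman for k >= 3 paired conditions, a signed-rank z for 2) or groups
(Kruskal–Wallis for k >= 3, a rank-sum z for 2) on participant-level
values.  Supra-threshold sites (p below the cluster-defining threshold,
default 0.05) are pooled into spatiotemporal clusters — neighboring
electrodes at the same time-bin, or the same electrode at adjacent
bins, with signed statistics clustered within sign — and each cluster
is summarized by its mass, the sum of its site statistics.  Cluster
significance is the rate of permutation-null *maximum* masses at least
as large as the observed mass, where the null is built by shuffling
condition labels within participant (paired) or group labels across
participants (unpaired).  Because tests operate on participant-level
condition means, the trial counts behind each cell are identical in
every permutation by construction.

Monte-Carlo p-values use the add-one convention ``(b + 1) / (n_perm + 1)``
so they are valid and never zero; whenever the full relabeling space is
small (<= 10,000 arrangements) the distribution is enumerated exhaustively
instead and the p-value is the exact rate including the identity.

All permutation fast paths exploit rank invariance: ranks (and tie
corrections) never change when labels are shuffled, so each permutation
only re-aggregates precomputed ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations, product

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .layout import SensorLayout

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterResult",
    "pointwise_stats",
    "form_clusters",
    "permutation_pvalues",
    "condition_dispersion_map",
    "roi_window_mean",
]

EXACT_LIMIT = 10_000  # enumerate the null when the relabeling space is this small


@dataclass
class StatMap:
    """Site-wise statistic and p-value over electrodes x time-bins."""

    stat: np.ndarray
    p: np.ndarray
    test: str  # friedman | kruskal | wilcoxon-paired | ranksum
    signed: bool

    def __post_init__(self) -> None:
        if self.stat.shape != self.p.shape:
            raise ValueError("stat and p must share shape")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class Cluster:
    sites: np.ndarray          # (n_sites, 2) array of (channel, time) indices
    mass: float                # sum of member statistics (signed for z tests)
    p: float | None = None     # permutation p-value


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cdt_alpha: float
    test: str
    exact: bool = False
    null_max: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p is not None and c.p <= alpha]


# ---------------------------------------------------------------------
# Vectorized site-wise rank statistics
# ---------------------------------------------------------------------

def _tie_counts_within(data: np.ndarray) -> np.ndarray:
    """Sum of (t^3 - t) over tie groups, per (participant, site) row.

    Uses the identity sum_t (t^3 - t) = sum_j (c_j^2 - 1), where c_j is
    the number of row elements equal to element j.
    """
    eq = data[:, :, None, :] == data[:, None, :, :]
    c = eq.sum(axis=2)
    return (c ** 2 - 1).sum(axis=1)  # participants x sites


def friedman_stats(ranks: np.ndarray, tie_c: np.ndarray) -> np.ndarray:
    """Tie-corrected Friedman chi-square from within-participant ranks.

    ``ranks``: participants x conditions x sites; ``tie_c``: per-site
    correction denominator factor (1 - sum(t^3-t)/(n k (k^2-1))).
    """
    n, k = ranks.shape[0], ranks.shape[1]
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rj ** 2).sum(axis=0) - 3.0 * n * (k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tie_c > 0, stat / tie_c, 0.0)
    return out


def _friedman_prep(data: np.ndarray):
    n, k = data.shape[0], data.shape[1]
    ranks = stats.rankdata(data, axis=1)
    t = _tie_counts_within(data).sum(axis=0)
    tie_c = 1.0 - t / (n * k * (k * k - 1.0))
    return ranks, tie_c


def _kruskal_prep(data: np.ndarray):
    """Ranks across participants per site plus tie correction factor."""
    N = data.shape[0]
    ranks = stats.rankdata(data, axis=0)
    t = _tie_counts_within(data[None, ...])[0]
    tie_c = 1.0 - t / (N ** 3 - N)
    return ranks, tie_c


def kruskal_stats(ranks: np.ndarray, tie_c: np.ndarray,
                  group_idx: list[np.ndarray]) -> np.ndarray:
    N = ranks.shape[0]
    h = np.zeros(ranks.shape[1:])
    for idx in group_idx:
        h += ranks[idx].sum(axis=0) ** 2 / len(idx)
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(tie_c > 0, h / tie_c, 0.0)


def signed_rank_stats(diff: np.ndarray):
    """Signed-rank z per site from participant difference maps.

    Zeros keep their rank but contribute neither to the sum nor the
    variance (conditional sign-flip null): z = sum(sign * rank) /
    sqrt(sum rank^2 over nonzero differences).
    """
    r = stats.rankdata(np.abs(diff), axis=0)
    sgn = np.sign(diff)
    g = sgn * r
    v = ((r ** 2) * (sgn != 0)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(v > 0, g.sum(axis=0) / np.sqrt(v), 0.0)
    return z, g, v


def ranksum_stats(ranks: np.ndarray, idx1: np.ndarray, n2: int) -> np.ndarray:
    """Tie-robust rank-sum z for group 1 vs group 2, per site."""
    N = ranks.shape[0]
    n1 = len(idx1)
    w = ranks[idx1].sum(axis=0)
    e = n1 * (N + 1) / 2.0
    var = (n1 * n2 / (N * (N - 1.0))
           * ((ranks ** 2).sum(axis=0) - N * (N + 1.0) ** 2 / 4.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, (w - e) / np.sqrt(var), 0.0)


def pointwise_stats(
    data: np.ndarray,
    design: str,
    groups: np.ndarray | None = None,
) -> StatMap:
    """Rank test at every (electrode, time-bin) site.

    Parameters
    ----------
    data : ndarray
        Paired design: participants x conditions x channels x times
        (participant-level condition ERPs).  Unpaired design:
        participants x channels x times, with ``groups`` giving one
        label per participant.
    design : {"paired", "unpaired"}
    groups : ndarray of labels, required for the unpaired design.
    """
    data = np.asarray(data, dtype=float)
    if design == "paired":
        if data.ndim != 4:
            raise ValueError("paired data must be participants x conditions "
                             "x channels x times")
        n, k = data.shape[:2]
        if n < 2 or k < 2:
            raise ValueError("need >= 2 participants and >= 2 conditions")
        flat = data.reshape(n, k, -1)
        if k == 2:
            z, _, _ = signed_rank_stats(flat[:, 0] - flat[:, 1])
            p = 2.0 * stats.norm.sf(np.abs(z))
            return StatMap(z.reshape(data.shape[2:]),
                           p.reshape(data.shape[2:]), "wilcoxon-paired", True)
        ranks, tie_c = _friedman_prep(flat)
        chi = friedman_stats(ranks, tie_c)
        p = np.where(chi > 0, stats.chi2.sf(chi, k - 1), 1.0)
        return StatMap(chi.reshape(data.shape[2:]),
                       p.reshape(data.shape[2:]), "friedman", False)
    if design == "unpaired":
        if data.ndim != 3 or groups is None:
            raise ValueError("unpaired data must be participants x channels "
                             "x times with group labels")
        groups = np.asarray(groups)
        labels = list(dict.fromkeys(groups))
        if len(labels) < 2 or min((groups == g).sum() for g in labels) < 2:
            raise ValueError("need >= 2 groups with >= 2 participants each")
        flat = data.reshape(data.shape[0], -1)
        ranks, tie_c = _kruskal_prep(flat)
        if len(labels) == 2:
            idx1 = np.flatnonzero(groups == labels[0])
            n2 = int((groups == labels[1]).sum())
            z = ranksum_stats(ranks, idx1, n2)
            p = 2.0 * stats.norm.sf(np.abs(z))
            return StatMap(z.reshape(data.shape[1:]),
                           p.reshape(data.shape[1:]), "ranksum", True)
        group_idx = [np.flatnonzero(groups == g) for g in labels]
        h = kruskal_stats(ranks, tie_c, group_idx)
        p = np.where(h > 0, stats.chi2.sf(h, len(labels) - 1), 1.0)
        return StatMap(h.reshape(data.shape[1:]),
                       p.reshape(data.shape[1:]), "kruskal", False)
    raise ValueError("design must be 'paired' or 'unpaired'")


# ---------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------

def _site_graph(adjacency: np.ndarray, n_times: int) -> sparse.csr_matrix:
    """Sparse graph over (channel, time) sites flattened C-order."""
    n_ch = adjacency.shape[0]
    n_sites = n_ch * n_times
    rows, cols = [], []
    # temporal edges: same channel, adjacent bins
    site = np.arange(n_sites).reshape(n_ch, n_times)
    rows.append(site[:, :-1].ravel())
    cols.append(site[:, 1:].ravel())
    # spatial edges: neighboring channels, same bin
    ci, cj = np.nonzero(np.triu(adjacency))
    for a, b in zip(ci, cj):
        rows.append(site[a])
        cols.append(site[b])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    g = sparse.coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)),
                          shape=(n_sites, n_sites))
    return (g + g.T).tocsr()


def _clusters_from_mask(stat_flat, mask_flat, graph, n_times):
    """Connected components of supra-threshold sites; returns Cluster list."""
    idx = np.flatnonzero(mask_flat)
    if idx.size == 0:
        return []
    sub = graph[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = idx[labels == comp]
        mass = float(stat_flat[members].sum())
        sites = np.column_stack(np.divmod(members, n_times))
        clusters.append(Cluster(sites=sites, mass=mass))
    return clusters


def _max_cluster_mass(stat_flat, mask_flat, graph):
    idx = np.flatnonzero(mask_flat)
    if idx.size == 0:
        return 0.0
    sub = graph[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=stat_flat[idx], minlength=n_comp)
    return float(np.abs(masses).max())


def _supra_masks(statmap_stat, threshold, signed):
    """Boolean masks of supra-threshold sites, split by sign when signed."""
    if signed:
        return [(statmap_stat > threshold), (statmap_stat < -threshold)]
    return [statmap_stat > threshold]


def _stat_threshold(test: str, cdt_alpha: float, k: int) -> float:
    if test in ("friedman", "kruskal"):
        return float(stats.chi2.isf(cdt_alpha, k - 1))
    return float(stats.norm.isf(cdt_alpha / 2.0))


def form_clusters(
    statmap: StatMap, layout: SensorLayout, cdt_alpha: float = 0.05
) -> ClusterResult:
    """Pool supra-threshold sites into spatiotemporal clusters.

    Sites enter a cluster when their site-wise p is below ``cdt_alpha``;
    connectivity is neighboring electrodes at the same time-bin or the
    same electrode at adjacent bins.  Signed statistics cluster within
    sign ("the same effect").  Cluster mass is the sum of member
    statistics; permutation p-values are attached by
    :func:`permutation_pvalues`.
    """
    n_ch, n_t = statmap.stat.shape
    if n_ch != layout.n_channels:
        raise ValueError("stat map does not match layout")
    graph = _site_graph(layout.adjacency, n_t)
    stat_flat = statmap.stat.ravel()
    supra = (statmap.p < cdt_alpha).ravel()
    clusters = []
    if statmap.signed:
        for sign_mask in (stat_flat > 0, stat_flat < 0):
            clusters += _clusters_from_mask(stat_flat, supra & sign_mask,
                                            graph, n_t)
    else:
        clusters = _clusters_from_mask(stat_flat, supra, graph, n_t)
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(clusters=clusters, n_permutations=0,
                         cdt_alpha=cdt_alpha, test=statmap.test)


# ---------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------

def _paired_relabelings(n: int, k: int):
    """All (k!)^n within-participant condition relabelings."""
    perms = list(permutations(range(k)))
    yield from product(perms, repeat=n)


def permutation_pvalues(
    data: np.ndarray,
    design: str,
    layout: SensorLayout,
    n_perm: int = 5000,
    cdt_alpha: float = 0.05,
    seed: int | None = None,
    groups: np.ndarray | None = None,
    method: str = "auto",
) -> ClusterResult:
    """Cluster permutation test over the whole time–scalp matrix.

    The null distribution of the maximum cluster mass is built by
    shuffling condition labels within participant (paired design) or
    group labels across participants (unpaired).  ``method`` is
    ``"auto"`` (enumerate exhaustively when the relabeling space has at
    most 10,000 arrangements, otherwise Monte Carlo), ``"exact"`` or
    ``"montecarlo"``.  Monte-Carlo p-values use (b+1)/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data = np.asarray(data, dtype=float)
    statmap = pointwise_stats(data, design, groups=groups)
    observed = form_clusters(statmap, layout, cdt_alpha)
    n_t = statmap.stat.shape[1]
    graph = _site_graph(layout.adjacency, n_t)
    rng = np.random.default_rng(seed)

    if design == "paired":
        n, k = data.shape[:2]
        flat = data.reshape(n, k, -1)
        thr = _stat_threshold(statmap.test, cdt_alpha, k)
        n_exact = math_factorial_pow(k, n)
        exact = (method == "exact"
                 or (method == "auto" and n_exact <= EXACT_LIMIT))
        if k == 2:
            _, g, v = signed_rank_stats(flat[:, 0] - flat[:, 1])
            sqrt_v = np.sqrt(np.where(v > 0, v, np.inf))

            def stat_for(signs):
                return (signs[:, None] * g).sum(axis=0) / sqrt_v

            if exact:
                signs_iter = (np.array(s, dtype=float)
                              for s in product((1.0, -1.0), repeat=n))
                null = [_max_cluster_mass(s, np.abs(s) > thr, graph)
                        for s in map(stat_for, signs_iter)]
                null = np.asarray(null)
                return _attach_p(observed, null, exact=True)
            null = np.empty(n_perm)
            for b in range(n_perm):
                signs = rng.choice([1.0, -1.0], size=n)
                s = stat_for(signs)
                null[b] = _max_cluster_mass(s, np.abs(s) > thr, graph)
            return _attach_p(observed, null, exact=False, n_perm=n_perm)

        ranks, tie_c = _friedman_prep(flat)

        def stat_for_perm(perm_idx):
            r = np.take_along_axis(ranks, perm_idx[:, :, None], axis=1)
            return friedman_stats(r, tie_c)

        if exact:
            null = []
            for labeling in _paired_relabelings(n, k):
                perm_idx = np.asarray(labeling)
                s = stat_for_perm(perm_idx)
                null.append(_max_cluster_mass(s, s > thr, graph))
            return _attach_p(observed, np.asarray(null), exact=True)
        base = np.tile(np.arange(k), (n, 1))
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.permuted(base, axis=1)
            s = stat_for_perm(perm_idx)
            null[b] = _max_cluster_mass(s, s > thr, graph)
        return _attach_p(observed, null, exact=False, n_perm=n_perm)

    # unpaired
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    N = data.shape[0]
    flat = data.reshape(N, -1)
    ranks, tie_c = _kruskal_prep(flat)
    sizes = [int((groups == g).sum()) for g in labels]
    thr = _stat_threshold(statmap.test, cdt_alpha, len(labels))
    two = len(labels) == 2

    def stat_for_assign(idx_lists):
        if two:
            s = ranksum_stats(ranks, idx_lists[0], len(idx_lists[1]))
            return s, np.abs(s) > thr
        s = kruskal_stats(ranks, tie_c, idx_lists)
        return s, s > thr

    from math import comb
    n_exact = 1
    remaining = N
    for sz in sizes[:-1]:
        n_exact *= comb(remaining, sz)
        remaining -= sz
    exact = (method == "exact" or (method == "auto" and n_exact <= EXACT_LIMIT))
    if exact:
        if len(labels) != 2:
            raise NotImplementedError("exact enumeration supports 2 groups")
        null = []
        all_idx = np.arange(N)
        for chosen in combinations(range(N), sizes[0]):
            i1 = np.asarray(chosen)
            i2 = np.setdiff1d(all_idx, i1, assume_unique=True)
            s, mask = stat_for_assign([i1, i2])
            null.append(_max_cluster_mass(s, mask, graph))
        return _attach_p(observed, np.asarray(null), exact=True)
    null = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(N)
        idx_lists = []
        start = 0
        for sz in sizes:
            idx_lists.append(order[start:start + sz])
            start += sz
        s, mask = stat_for_assign(idx_lists)
        null[b] = _max_cluster_mass(s, mask, graph)
    return _attach_p(observed, null, exact=False, n_perm=n_perm)


def math_factorial_pow(k: int, n: int) -> float:
    """(k!)^n with overflow-safe saturation above the exact-enumeration cap."""
    import math
    fact = math.factorial(k)
    total = 1
    for _ in range(n):
        total *= fact
        if total > 10 * EXACT_LIMIT:
            return float(total)
    return float(total)


def _attach_p(observed: ClusterResult, null: np.ndarray, exact: bool,
              n_perm: int | None = None) -> ClusterResult:
    for c in observed.clusters:
        b = int((np.abs(null) >= abs(c.mass)).sum())
        c.p = b / null.size if exact else (b + 1) / (null.size + 1)
    observed.n_permutations = null.size if exact else (n_perm or null.size)
    observed.exact = exact
    observed.null_max = null
    return observed


# ---------------------------------------------------------------------
# Dispersion (group x condition interaction) and ROI helpers
# ---------------------------------------------------------------------

def condition_dispersion_map(
    data: np.ndarray,
    groups: np.ndarray,
    layout: SensorLayout,
    n_perm: int = 5000,
    cdt_alpha: float = 0.05,
    seed: int | None = None,
):
    """Per-participant SD among condition means, compared between groups.

    ``data`` is participants x conditions x channels x times.  The SD
    across the condition axis summarizes each participant's condition
    modulation at every site; groups are then compared with a rank-sum
    cluster permutation over group labels.  Returns ``(sd_maps,
    ClusterResult)``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[1] < 2:
        raise ValueError("need participants x conditions x channels x times "
                         "with >= 2 conditions")
    sd_maps = data.std(axis=1, ddof=1)
    result = permutation_pvalues(sd_maps, "unpaired", layout, n_perm=n_perm,
                                 cdt_alpha=cdt_alpha, seed=seed, groups=groups)
    return sd_maps, result


def roi_window_mean(
    data: np.ndarray,
    times_ms: np.ndarray,
    layout: SensorLayout,
    roi: str | list[str],
    window_ms: tuple[float, float],
) -> np.ndarray:
    """Mean over ROI electrodes and a time window, per leading axis entry.

    ``data`` is ... x channels x times (e.g. participants x conditions x
    channels x times); returns the leading axes reduced over the ROI.
    Used for follow-up tests such as a right-parietal 450–630 ms ROI.
    """
    times_ms = np.asarray(times_ms)
    idx = (layout.roi_indices(roi) if isinstance(roi, str)
           else layout.indices(roi))
    lo, hi = window_ms
    tmask = (times_ms >= lo) & (times_ms <= hi)
    if not tmask.any():
        raise ValueError("empty time window")
    return data[..., idx, :][..., tmask].mean(axis=(-2, -1))
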