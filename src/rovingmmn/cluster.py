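"""Spatio-temporal cluster-based permutation tests.

Mass-univariate testing over (channel, time) cells with cluster-level
correction: cells exceeding a parametric threshold (t or F quantile at the
cluster-forming alpha, from the design's degrees of freedom) are grouped into
connected components, where connectivity means temporal adjacency within a
channel or sensor adjacency at the same time point. The cluster statistic is
the mass (sum of cell statistics). The null distribution is the maximum
absolute cluster mass per permutation -- per-subject sign flips of difference
ERPs for the paired t test, within-subject condition-label permutations for
the repeated-measures F test. Cluster p-values use the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_permutations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .montage import Montage

__all__ = [
    "AdjacencyGraph",
    "ClusterTestConfig",
    "Cluster",
    "ClusterTestResult",
    "channel_adjacency",
    "stat_map_paired_t",
    "stat_map_rm_F",
    "form_clusters",
    "permutation_test",
]

# Chosen so the default 30-channel montage has median sensor degree 4-6 and a
# connected neighbor graph.
DEFAULT_ADJACENCY_RADIUS = 0.48


@dataclass(frozen=True)
class AdjacencyGraph:
    names: tuple[str, ...]
    matrix: np.ndarray  # boolean (n, n), symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.names):
            raise ValueError("adjacency matrix shape mismatch")
        if np.any(m != m.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(m)):
            raise ValueError("adjacency must be irreflexive")

    def degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def is_connected(self) -> bool:
        n, _ = connected_components(sparse.csr_matrix(self.matrix), directed=False)
        return n == 1


def channel_adjacency(
    montage: Montage, radius: float = DEFAULT_ADJACENCY_RADIUS
) -> AdjacencyGraph:
    """Sensors closer than ``radius`` (2-D Euclidean) are neighbors."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if montage.n_channels < 2:
        raise ValueError("need at least two channels")
    pos = montage.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    matrix = (d < radius) & ~np.eye(montage.n_channels, dtype=bool)
    return AdjacencyGraph(names=montage.names, matrix=matrix)


@dataclass(frozen=True)
class ClusterTestConfig:
    n_permutations: int = 1024
    cluster_alpha: float = 0.05
    test: str = "paired_t"  # or "rm_F"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.test not in ("paired_t", "rm_F"):
            raise ValueError("test must be 'paired_t' or 'rm_F'")


@dataclass
class Cluster:
    channels: np.ndarray  # channel index per member cell
    times: np.ndarray  # time index per member cell
    mass: float
    sign: int  # +1 / -1 for t clusters, +1 for F
    p_value: float | None = None

    @property
    def n_cells(self) -> int:
        return len(self.channels)

    @property
    def n_sensors(self) -> int:
        return len(np.unique(self.channels))

    def time_extent(self) -> tuple[int, int]:
        return int(self.times.min()), int(self.times.max())

    def summary(self, times_ms: np.ndarray, names: tuple[str, ...]) -> dict:
        t0, t1 = self.time_extent()
        return {
            "t_start_ms": float(times_ms[t0]),
            "t_end_ms": float(times_ms[t1]),
            "n_sensors": self.n_sensors,
            "channels": sorted({names[c] for c in self.channels}),
            "mass": self.mass,
            "sign": self.sign,
            "p": self.p_value,
        }


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    stat_map: np.ndarray  # (n_channels, n_times)
    threshold: float
    null_max_mass: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < alpha]

    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def stat_map_paired_t(diffs: np.ndarray, cluster_alpha: float = 0.05):
    """Cell-wise one-sample t on within-subject differences.

    ``diffs``: (n_subjects, n_channels, n_times). Zero-variance cells get
    t = 0 with a warning: they carry no evidence and must not seed clusters.
    Returns (t_map, threshold) with the two-sided t quantile at
    ``cluster_alpha`` and df = n - 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero):
        warnings.warn("zero-variance cells set to t=0", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    threshold = float(t_dist.ppf(1 - cluster_alpha / 2, df=n - 1))
    return t_map, threshold


def stat_map_rm_F(data: np.ndarray, cluster_alpha: float = 0.05):
    """Cell-wise one-way repeated-measures F.

    ``data``: (n_subjects, n_conditions, n_channels, n_times).
    F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(n-1)).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape[:2]
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = data.mean(axis=(0, 1))
    cond_mean = data.mean(axis=0)
    subj_mean = data.mean(axis=1)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_tot = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_int = ss_tot - ss_cond - ss_subj
    ms_cond = ss_cond / (k - 1)
    ms_int = ss_int / ((k - 1) * (n - 1))
    zero = ms_int <= 0
    if np.any(zero):
        warnings.warn("zero-variance cells set to F=0", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_map = np.where(zero, 0.0, ms_cond / ms_int)
    threshold = float(f_dist.ppf(1 - cluster_alpha, dfn=k - 1, dfd=(k - 1) * (n - 1)))
    return f_map, threshold


def _cell_graph(supra: np.ndarray, adjacency: np.ndarray) -> sparse.csr_matrix:
    """Connectivity among supra-threshold cells of a (channels x times) mask."""
    n_ch, n_t = supra.shape
    idx = -np.ones(supra.shape, dtype=np.int64)
    order = np.flatnonzero(supra.ravel())
    idx.ravel()[order] = np.arange(len(order))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    # temporal neighbors within a channel
    both = supra[:, :-1] & supra[:, 1:]
    c, t = np.nonzero(both)
    rows.append(idx[c, t])
    cols.append(idx[c, t + 1])
    # sensor neighbors at the same time (each unordered pair once)
    a_idx, b_idx = np.nonzero(np.triu(adjacency, k=1))
    for a, b in zip(a_idx, b_idx):
        t = np.nonzero(supra[a] & supra[b])[0]
        if len(t):
            rows.append(idx[a, t])
            cols.append(idx[b, t])

    n = len(order)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    return sparse.csr_matrix(
        (np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n)
    )


def _label_clusters(supra: np.ndarray, adjacency: np.ndarray):
    """(cell indices, component labels) for one supra-threshold mask."""
    cells = np.nonzero(supra)
    if len(cells[0]) == 0:
        return cells, np.empty(0, dtype=np.int64), 0
    graph = _cell_graph(supra, adjacency)
    n_comp, labels = connected_components(graph, directed=False)
    return cells, labels, n_comp


def form_clusters(
    stat_map: np.ndarray,
    threshold: float,
    adjacency: AdjacencyGraph,
    tail: str = "two-sided",
) -> list[Cluster]:
    """Group supra-threshold cells into connected clusters.

    ``tail='two-sided'`` clusters positive and negative exceedances
    separately (paired t); ``tail='one-sided'`` clusters ``stat > threshold``
    only (F). Clusters are returned sorted by descending |mass|.
    """
    adj = adjacency.matrix
    if stat_map.shape[0] != adj.shape[0]:
        raise ValueError("stat_map channels do not match adjacency")
    masks = [(stat_map > threshold, 1)]
    if tail == "two-sided":
        masks.append((stat_map < -threshold, -1))
    elif tail != "one-sided":
        raise ValueError("tail must be 'two-sided' or 'one-sided'")

    clusters: list[Cluster] = []
    for supra, sign in masks:
        (ch, t), labels, n_comp = _label_clusters(supra, adj)
        for comp in range(n_comp):
            member = labels == comp
            clusters.append(
                Cluster(
                    channels=ch[member],
                    times=t[member],
                    mass=float(stat_map[ch[member], t[member]].sum()),
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return clusters


def _max_cluster_mass(
    stat_map: np.ndarray, threshold: float, adjacency: np.ndarray, tail: str
) -> float:
    """Largest |mass| over clusters of one permuted map (0 if none)."""
    best = 0.0
    masks = [stat_map > threshold]
    if tail == "two-sided":
        masks.append(stat_map < -threshold)
    for supra in masks:
        (ch, t), labels, n_comp = _label_clusters(supra, adjacency)
        if n_comp:
            masses = np.bincount(labels, weights=stat_map[ch, t], minlength=n_comp)
            best = max(best, float(np.abs(masses).max()))
    return best


def permutation_test(
    data: np.ndarray,
    adjacency: AdjacencyGraph,
    cfg: ClusterTestConfig | None = None,
) -> ClusterTestResult:
    """Cluster-based permutation test.

    ``cfg.test='paired_t'``: ``data`` is (n_subjects, n_channels, n_times)
    within-subject difference ERPs; the null randomly flips each subject's
    sign. ``cfg.test='rm_F'``: ``data`` is (n_subjects, n_conditions,
    n_channels, n_times); the null permutes condition labels within subject.
    Deterministic under ``cfg.seed``. The identity permutation is not drawn
    explicitly; it enters through the add-one p-value correction.
    """
    cfg = cfg or ClusterTestConfig()
    rng = np.random.default_rng(cfg.seed)
    data = np.asarray(data, dtype=float)

    if cfg.test == "paired_t":
        n = data.shape[0]
        if 2**n <= cfg.n_permutations:
            warnings.warn(
                f"only {2 ** n} distinct sign flips for {cfg.n_permutations} "
                "permutations",
                RuntimeWarning,
                stacklevel=2,
            )
        stat_map, threshold = stat_map_paired_t(data, cfg.cluster_alpha)
        tail = "two-sided"
        clusters = form_clusters(stat_map, threshold, adjacency, tail)

        flat = data.reshape(n, -1)
        sumsq = (flat**2).sum(axis=0)
        null = np.empty(cfg.n_permutations)
        with np.errstate(divide="ignore", invalid="ignore"):
            for i in range(cfg.n_permutations):
                signs = rng.choice([-1.0, 1.0], size=n)
                mean = signs @ flat / n
                var = (sumsq - n * mean**2) / (n - 1)
                t_flat = np.where(var <= 0, 0.0, mean / np.sqrt(var / n))
                null[i] = _max_cluster_mass(
                    t_flat.reshape(data.shape[1:]), threshold, adjacency.matrix, tail
                )
    else:
        n, k = data.shape[:2]
        stat_map, threshold = stat_map_rm_F(data, cfg.cluster_alpha)
        tail = "one-sided"
        clusters = form_clusters(stat_map, threshold, adjacency, tail)

        flat = data.reshape(n, k, -1)
        grand = flat.mean(axis=(0, 1))
        subj_mean = flat.mean(axis=1)
        ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
        ss_tot = ((flat - grand) ** 2).sum(axis=(0, 1))
        dfn, dfd = k - 1, (k - 1) * (n - 1)
        null = np.empty(cfg.n_permutations)
        with np.errstate(divide="ignore", invalid="ignore"):
            for i in range(cfg.n_permutations):
                perms = np.argsort(rng.random((n, k)), axis=1)
                permuted = np.take_along_axis(flat, perms[..., None], axis=1)
                cond_mean = permuted.mean(axis=0)
                ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=0)
                ms_int = (ss_tot - ss_cond - ss_subj) / dfd
                f_flat = np.where(ms_int <= 0, 0.0, (ss_cond / dfn) / ms_int)
                null[i] = _max_cluster_mass(
                    f_flat.reshape(data.shape[2:]), threshold, adjacency.matrix, tail
                )

    for c in clusters:
        c.p_value = float((1 + np.sum(null >= abs(c.mass))) / (1 + cfg.n_permutations))
    return ClusterTestResult(
        clusters=clusters, stat_map=stat_map, threshold=threshold, null_max_mass=null
    )
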