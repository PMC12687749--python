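"""Temporal denoising of expression points.

Source reconstruction blurs cortical activity, so a single underlying
effect appears as a cluster of significant points jittered along the
latency axis.  Denoising assigns each significant point of a transform
to a temporal cluster (or tags it as an anomaly), then keeps only the
most significant point per cluster — the *focus* — as the effect's
representative latency.

Five strategies are provided, all clustering on latency alone:

``mp``
    Max pooling: fixed-width latency bins; bins with fewer than a
    threshold number of points are discarded as anomalies.
``amp``
    Adaptive max pooling: max pooling followed by transitive merging of
    adjacent significant bins, giving variable-width clusters.
``gmm``
    1-D Gaussian mixture with the number of components chosen by AIC
    grid search, with a retry loop guarding against singular
    (zero-variance) components.
``meanshift``
    Kernel-density mode seeking with a fixed bandwidth.
``dbscan``
    Density-based clustering on |Δlatency| with noise points flagged as
    anomalies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import DBSCAN, MeanShift
from sklearn.mixture import GaussianMixture

from .expression import ExpressionPoint, ExpressionSet, ParameterError

__all__ = [
    "ANOMALY",
    "ClusterResult",
    "MaxPoolConfig",
    "GMMConfig",
    "MeanShiftConfig",
    "DBSCANConfig",
    "preprocess",
    "max_pool",
    "adaptive_max_pool",
    "gmm_cluster",
    "mean_shift_cluster",
    "dbscan_cluster",
    "select_foci",
    "denoise_expression",
    "default_config",
    "STRATEGIES",
]

#: Label for points judged not to belong to any cluster.
ANOMALY = -1


@dataclass
class ClusterResult:
    """Cluster labels for one transform's points, plus the selected foci.

    ``labels[i]`` is the cluster of ``points[i]`` (consecutive integers
    from 0, ordered by ascending cluster latency) or :data:`ANOMALY`.
    """

    transform: str
    points: list[ExpressionPoint]
    labels: np.ndarray
    foci: list[ExpressionPoint] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len({l for l in self.labels.tolist() if l != ANOMALY})

    def members(self, label: int) -> list[ExpressionPoint]:
        return [p for p, l in zip(self.points, self.labels) if l == label]


@dataclass
class MaxPoolConfig:
    """Max pooling: bin size ``b`` (ms), exclusion threshold ``θ`` (min points).

    The default bin of 50 ms covers a full expression cluster at the
    characteristic latency jitter of these data (~±2σ with σ = 10 ms),
    so a single effect is not fragmented across bins.
    """

    bin_size_ms: float = 50.0
    min_points: int = 2
    bin_anchor_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_size_ms <= 0:
            raise ParameterError("bin_size_ms must be > 0")
        if self.min_points < 1:
            raise ParameterError("min_points must be >= 1")


@dataclass
class GMMConfig:
    """1-D Gaussian mixture with AIC model selection."""

    max_components: int = 5
    n_init: int = 3
    max_iter: int = 200
    max_retries: int = 3
    # A component narrower than the 1 ms latency resolution is a
    # degenerate splinter: treated as singular and refit.
    covariance_floor: float = 1.0  # ms^2
    min_cluster_points: int = 1

    def __post_init__(self) -> None:
        if min(self.max_components, self.n_init, self.max_iter, self.min_cluster_points) < 1:
            raise ParameterError("GMMConfig integer fields must be >= 1")
        if self.max_retries < 0 or self.covariance_floor <= 0:
            raise ParameterError("invalid GMMConfig")


@dataclass
class MeanShiftConfig:
    bandwidth_ms: float = 15.0
    max_iter: int = 300
    min_cluster_points: int = 1

    def __post_init__(self) -> None:
        if self.bandwidth_ms <= 0:
            raise ParameterError("bandwidth_ms must be > 0")
        if self.max_iter < 1 or self.min_cluster_points < 1:
            raise ParameterError("invalid MeanShiftConfig")


@dataclass
class DBSCANConfig:
    eps_ms: float = 10.0
    min_samples: int = 2

    def __post_init__(self) -> None:
        if self.eps_ms <= 0:
            raise ParameterError("eps_ms must be > 0")
        if self.min_samples < 1:
            raise ParameterError("min_samples must be >= 1")


def preprocess(
    points: Sequence[ExpressionPoint], threshold_logp: float
) -> list[ExpressionPoint]:
    """Drop insignificant points.

    Clustering downstream uses latency only; surprisal is kept on the
    points as metadata for focus selection.
    """
    return [p for p in points if p.surprisal >= threshold_logp]


def _latencies(points: Sequence[ExpressionPoint]) -> np.ndarray:
    return np.array([p.latency_ms for p in points], dtype=float)


def _canonical_labels(
    points: Sequence[ExpressionPoint], raw_labels: np.ndarray
) -> np.ndarray:
    """Relabel clusters as 0..k-1 in order of ascending mean latency."""
    lat = _latencies(points)
    keys = sorted(
        {int(l) for l in raw_labels.tolist() if l != ANOMALY},
        key=lambda l: (float(lat[raw_labels == l].mean()), l),
    )
    remap = {old: new for new, old in enumerate(keys)}
    return np.array(
        [remap[int(l)] if l != ANOMALY else ANOMALY for l in raw_labels], dtype=int
    )


def _finalize(
    transform: str, points: Sequence[ExpressionPoint], labels: np.ndarray
) -> ClusterResult:
    labels = _canonical_labels(points, labels)
    result = ClusterResult(transform, list(points), labels)
    result.foci = select_foci(result)
    return result


def _apply_min_cluster_size(labels: np.ndarray, min_points: int) -> np.ndarray:
    if min_points <= 1:
        return labels
    labels = labels.copy()
    for l in set(labels.tolist()):
        if l != ANOMALY and int((labels == l).sum()) < min_points:
            labels[labels == l] = ANOMALY
    return labels


def max_pool(
    points: Sequence[ExpressionPoint], cfg: MaxPoolConfig, transform: str = ""
) -> ClusterResult:
    """Fixed-bin max pooling.

    Bins are half-open ``[anchor + k*b, anchor + (k+1)*b)``; bins holding
    at least ``min_points`` points become clusters, the rest of the
    points are anomalies.
    """
    if not points:
        return ClusterResult(transform, [], np.array([], dtype=int))
    lat = _latencies(points)
    bins = np.floor((lat - cfg.bin_anchor_ms) / cfg.bin_size_ms).astype(int)
    counts = {b: int((bins == b).sum()) for b in set(bins.tolist())}
    good = {b: k for k, b in enumerate(sorted(b for b, c in counts.items() if c >= cfg.min_points))}
    labels = np.array([good.get(b, ANOMALY) for b in bins.tolist()], dtype=int)
    return _finalize(transform, points, labels)


def adaptive_max_pool(
    points: Sequence[ExpressionPoint], cfg: MaxPoolConfig, transform: str = ""
) -> ClusterResult:
    """Max pooling with transitive merging of adjacent significant bins.

    ``bin_size_ms`` acts as a minimum cluster width: significant bins
    with consecutive indices are merged into a single variable-width
    cluster.
    """
    if not points:
        return ClusterResult(transform, [], np.array([], dtype=int))
    lat = _latencies(points)
    bins = np.floor((lat - cfg.bin_anchor_ms) / cfg.bin_size_ms).astype(int)
    counts = {b: int((bins == b).sum()) for b in set(bins.tolist())}
    good = sorted(b for b, c in counts.items() if c >= cfg.min_points)
    # Merge runs of consecutive significant bin indices.
    bin_to_cluster: dict[int, int] = {}
    cluster = -1
    prev = None
    for b in good:
        if prev is None or b != prev + 1:
            cluster += 1
        bin_to_cluster[b] = cluster
        prev = b
    labels = np.array(
        [bin_to_cluster.get(b, ANOMALY) for b in bins.tolist()], dtype=int
    )
    return _finalize(transform, points, labels)


def _fit_gmm_grid(
    x: np.ndarray, cfg: GMMConfig, rng: np.random.Generator
) -> GaussianMixture | None:
    """AIC grid search over component counts with a singularity retry loop."""
    n = x.shape[0]
    best: tuple[float, GaussianMixture] | None = None
    for k in range(1, min(cfg.max_components, n) + 1):
        model = None
        for _ in range(cfg.max_retries + 1):
            seed = int(rng.integers(0, 2**31 - 1))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    candidate = GaussianMixture(
                        n_components=k,
                        n_init=cfg.n_init,
                        max_iter=cfg.max_iter,
                        covariance_type="full",
                        reg_covar=1e-12,
                        random_state=seed,
                    ).fit(x)
            except Exception:  # numerically degenerate fit: retry
                continue
            if np.min(candidate.covariances_) < cfg.covariance_floor:
                continue  # singular component: refit with a fresh init
            model = candidate
            break
        if model is None:
            continue  # all retries singular: drop this K from the grid
        aic = model.aic(x)
        if best is None or aic < best[0]:
            best = (aic, model)
    return None if best is None else best[1]


def gmm_cluster(
    points: Sequence[ExpressionPoint],
    cfg: GMMConfig,
    seed: int | None = None,
    transform: str = "",
) -> ClusterResult:
    if not points:
        return ClusterResult(transform, [], np.array([], dtype=int))
    rng = np.random.default_rng(seed)
    x = _latencies(points).reshape(-1, 1)
    model = _fit_gmm_grid(x, cfg, rng)
    if model is None:
        warnings.warn(
            f"all mixture fits singular for transform {transform!r}; "
            "falling back to a single cluster"
        )
        labels = np.zeros(len(points), dtype=int)
    else:
        labels = model.predict(x).astype(int)
    labels = _apply_min_cluster_size(labels, cfg.min_cluster_points)
    return _finalize(transform, points, labels)


def mean_shift_cluster(
    points: Sequence[ExpressionPoint],
    cfg: MeanShiftConfig,
    seed: int | None = None,
    transform: str = "",
) -> ClusterResult:
    if not points:
        return ClusterResult(transform, [], np.array([], dtype=int))
    x = _latencies(points).reshape(-1, 1)
    ms = MeanShift(bandwidth=cfg.bandwidth_ms, max_iter=cfg.max_iter)
    labels = ms.fit_predict(x).astype(int)
    labels = _apply_min_cluster_size(labels, cfg.min_cluster_points)
    return _finalize(transform, points, labels)


def dbscan_cluster(
    points: Sequence[ExpressionPoint], cfg: DBSCANConfig, transform: str = ""
) -> ClusterResult:
    if not points:
        return ClusterResult(transform, [], np.array([], dtype=int))
    x = _latencies(points).reshape(-1, 1)
    labels = DBSCAN(eps=cfg.eps_ms, min_samples=cfg.min_samples).fit_predict(x)
    labels = np.where(labels < 0, ANOMALY, labels).astype(int)
    return _finalize(transform, points, labels)


def select_foci(result: ClusterResult) -> list[ExpressionPoint]:
    """The most significant point of each cluster, sorted by latency.

    Ties on surprisal go to the earlier latency, then the lower hexel
    id, so output is deterministic.
    """
    foci = []
    for label in sorted({int(l) for l in result.labels.tolist() if l != ANOMALY}):
        members = result.members(label)
        members.sort(key=lambda p: (-p.surprisal, p.latency_ms, p.hexel_id))
        foci.append(members[0])
    foci.sort(key=lambda p: (p.latency_ms, p.hexel_id))
    return foci


def _run_mp(points, cfg, seed, transform):
    return max_pool(points, cfg, transform)


def _run_amp(points, cfg, seed, transform):
    return adaptive_max_pool(points, cfg, transform)


def _run_gmm(points, cfg, seed, transform):
    return gmm_cluster(points, cfg, seed, transform)


def _run_meanshift(points, cfg, seed, transform):
    return mean_shift_cluster(points, cfg, seed, transform)


def _run_dbscan(points, cfg, seed, transform):
    return dbscan_cluster(points, cfg, transform)


#: strategy name -> (config type, runner)
STRATEGIES: dict[str, tuple[type, Callable]] = {
    "mp": (MaxPoolConfig, _run_mp),
    "amp": (MaxPoolConfig, _run_amp),
    "gmm": (GMMConfig, _run_gmm),
    "meanshift": (MeanShiftConfig, _run_meanshift),
    "dbscan": (DBSCANConfig, _run_dbscan),
}


def default_config(strategy: str):
    if strategy not in STRATEGIES:
        raise ParameterError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
        )
    return STRATEGIES[strategy][0]()


def denoise_expression(
    expr: ExpressionSet,
    strategy: str = "mp",
    cfg=None,
    seed: int | None = None,
    threshold_logp: float | None = None,
    return_clusters: bool = False,
):
    """Denoise every transform of an expression set with one shared configuration.

    Returns a mapping ``transform -> list of foci`` (empty list when no
    significant points survive), or ``transform -> ClusterResult`` when
    ``return_clusters`` is true.  The same configuration is applied to
    all transforms (transform-agnostic denoising).
    """
    if strategy not in STRATEGIES:
        raise ParameterError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
        )
    cfg_type, runner = STRATEGIES[strategy]
    if cfg is None:
        cfg = cfg_type()
    threshold = threshold_logp
    if threshold is None:
        threshold = expr.alpha_threshold_logp if expr.alpha_threshold_logp is not None else 0.0
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    out: dict[str, ClusterResult] = {}
    for i, transform in enumerate(sorted(expr.transforms_present)):
        pts = preprocess(expr.points_for(transform), threshold)
        sub_seed = int(np.random.SeedSequence((ss.entropy, i)).generate_state(1)[0] % (2**31))
        out[transform] = runner(pts, cfg, sub_seed, transform)
    if return_clusters:
        return out
    return {t: r.foci for t, r in out.items()}
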