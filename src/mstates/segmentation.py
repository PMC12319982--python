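"""Polarity-invariant microstate segmentation.

The segmentation stage reduces average-referenced EEG to a small set of
prototype topographies: compute the global field power (GFP), sample the
scalp maps at GFP maxima (where topographic signal-to-noise is highest),
and cluster those maps with a modified k-means in which a cluster "center"
is the unit-norm principal eigenvector of its members' scatter matrix and
assignment maximizes the squared projection.  Squaring makes the procedure
blind to map polarity: a topography and its sign-flipped twin belong to the
same microstate.

Model order is scored by the global explained variance (GEV, higher is
better) and by a cross-validation criterion penalizing the number of
classes (lower is better), evaluated over a scan of K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_ingest import EpochedEEG, EmptyResultError, ValidationError

__all__ = [
    "GFPSeries",
    "PeakSet",
    "PrototypeSet",
    "SegmentationFit",
    "spatial_correlation",
    "compute_gfp",
    "pick_gfp_peaks",
    "modified_kmeans",
    "compute_gev",
    "compute_cv_criterion",
    "scan_k",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GFPSeries:
    """Per-sample global field power (spatial SD of the scalp map), in µV."""

    values: np.ndarray  # n_epochs x n_samples
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("GFP values must be non-negative")


@dataclass
class PeakSet:
    """Scalp maps sampled at GFP maxima."""

    maps: np.ndarray  # n_peaks x n_channels, average-referenced µV
    gfp_at_peak: np.ndarray
    source: np.ndarray  # n_peaks x 2 (epoch, sample) indices

    @property
    def n_peaks(self) -> int:
        return self.maps.shape[0]


@dataclass
class PrototypeSet:
    """K zero-mean, unit-norm topographic maps, polarity-equivalent."""

    maps: np.ndarray  # K x n_channels
    channel_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        means = self.maps.mean(axis=1)
        norms = np.linalg.norm(self.maps, axis=1)
        if not np.allclose(means, 0.0, atol=1e-8):
            raise ValidationError("prototype maps must have zero channel mean")
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValidationError("prototype maps must have unit norm")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "K": self.K,
            "channel_names": list(self.channel_names),
            "maps": self.maps.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrototypeSet":
        payload = json.loads(Path(path).read_text())
        return cls(maps=np.array(payload["maps"]),
                   channel_names=payload.get("channel_names", []))


@dataclass
class SegmentationFit:
    """Result of one modified-k-means clustering of a peak set."""

    prototypes: PrototypeSet
    labels: np.ndarray  # over peak maps
    sigma2_hat: float
    gev: float
    cv: float
    n_restarts_used: int
    converged: np.ndarray  # per-restart flags

    def __post_init__(self) -> None:
        if not (0.0 <= self.gev <= 1.0 + 1e-9):
            raise ValidationError(f"GEV out of range: {self.gev}")
        if self.sigma2_hat < 0:
            raise ValidationError("sigma2_hat must be >= 0")


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two scalp maps across channels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# GFP and peak picking
# ---------------------------------------------------------------------------

def compute_gfp(ep: EpochedEEG) -> GFPSeries:
    """GFP(t) = sqrt((1/C) Σ_c (v_c(t) − v̄(t))²) — spatial SD per sample."""
    if ep.n_channels < 2:
        raise ValidationError("GFP requires >= 2 channels")
    centered = ep.epochs - ep.epochs.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered**2, axis=1))
    return GFPSeries(values=gfp, fs=ep.fs)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    # interior samples strictly greater than both neighbors
    if x.size < 3:
        return np.array([], dtype=np.int64)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def pick_gfp_peaks(
    gfp: GFPSeries,
    ep: EpochedEEG,
    min_distance_ms: float = 10.0,
    n_peaks: int = 1000,
    seed: int = 0,
) -> PeakSet:
    """Select scalp maps at GFP maxima, thinned to a minimum peak spacing.

    Interior strict local maxima are found within each epoch, then greedily
    thinned from the highest GFP downward so that retained peaks in the
    same epoch are at least ``min_distance_ms`` apart (ties broken by the
    earlier sample).  If more than ``n_peaks`` survive, a seeded uniform
    subsample of exactly ``n_peaks`` is returned, in (epoch, sample) order.
    """
    values = gfp.values
    min_dist = max(1, int(round(min_distance_ms * gfp.fs / 1000.0)))
    kept_epochs: list[int] = []
    kept_samples: list[int] = []
    for e in range(values.shape[0]):
        cand = _local_maxima(values[e])
        if cand.size == 0:
            continue
        order = np.lexsort((cand, -values[e][cand]))  # height desc, sample asc
        kept: list[int] = []
        for idx in cand[order]:
            if all(abs(idx - k) >= min_dist for k in kept):
                kept.append(int(idx))
        kept.sort()
        kept_epochs.extend([e] * len(kept))
        kept_samples.extend(kept)
    if not kept_samples:
        raise EmptyResultError("no GFP peaks found")
    source = np.column_stack([kept_epochs, kept_samples]).astype(np.int64)
    if source.shape[0] > n_peaks:
        rng = np.random.default_rng(seed)
        sel = np.sort(rng.choice(source.shape[0], size=n_peaks, replace=False))
        source = source[sel]
    maps = ep.epochs[source[:, 0], :, source[:, 1]]
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp_at = values[source[:, 0], source[:, 1]]
    return PeakSet(maps=maps, gfp_at_peak=gfp_at, source=source)


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

def _principal_direction(V: np.ndarray, init: np.ndarray | None = None,
                         tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """Unit-norm principal eigenvector of Vᵀ V for members V (n x C).

    Power iteration applied through V (cost O(nC) per step), warm-started
    from the previous prototype when available.
    """
    n, C = V.shape
    if n == 1:
        v = V[0]
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else np.ones(C) / np.sqrt(C)
    a = init.copy() if init is not None else V[0].copy()
    nrm = np.linalg.norm(a)
    if nrm == 0:
        a = np.ones(C)
        nrm = np.linalg.norm(a)
    a /= nrm
    for _ in range(max_iter):
        b = V.T @ (V @ a)
        nrm = np.linalg.norm(b)
        if nrm == 0:
            return a
        b /= nrm
        if abs(abs(b @ a) - 1.0) < tol:
            a = b
            break
        a = b
    return a


def _canonical_sign(maps: np.ndarray) -> np.ndarray:
    # fix the arbitrary polarity: largest-|value| channel made positive
    maps = maps.copy()
    for k in range(maps.shape[0]):
        i = int(np.argmax(np.abs(maps[k])))
        if maps[k, i] < 0:
            maps[k] = -maps[k]
    return maps


def _sigma2(V: np.ndarray, prototypes: np.ndarray, labels: np.ndarray) -> float:
    C = V.shape[1]
    proj = np.einsum("tc,tc->t", V, prototypes[labels])
    resid = np.einsum("tc,tc->t", V, V) - proj**2
    # cancellation can leave a tiny negative residual in the noise-free case
    return float(max(resid.sum(), 0.0) / (V.shape[0] * (C - 1)))


def modified_kmeans(
    peaks: PeakSet,
    K: int,
    n_restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-7,
    seed: int = 0,
) -> SegmentationFit:
    """Polarity-invariant modified k-means over GFP-peak maps.

    Per restart: initialize prototypes as K distinct randomly chosen peak
    maps (normalized); alternate (i) assignment L(t) = argmax_k (a_kᵀ v_t)²
    (ties to the lowest class index) and (ii) prototype update a_k ← the
    unit-norm principal eigenvector of the scatter of cluster k's members,
    until the relative change of the residual noise variance

        σ̂² = Σ_t (‖v_t‖² − (a_{L(t)}ᵀ v_t)²) / (T (C − 1))

    drops below ``tol`` or ``max_iter`` is reached.  An emptied cluster is
    re-seeded from the currently worst-fit map.  The restart with minimal
    σ̂² wins.  Defaults follow common practice for infant resting EEG:
    50 stochastic restarts, at most 1000 iterations each.
    """
    V = np.asarray(peaks.maps, dtype=float)
    T, C = V.shape
    if K > T:
        raise ValidationError(f"K={K} exceeds the number of peak maps ({T})")
    rng = np.random.default_rng(seed)
    sq_norm = np.einsum("tc,tc->t", V, V)
    denom = T * (C - 1)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    converged = np.zeros(n_restarts, dtype=bool)
    for r in range(n_restarts):
        # alternate data-point seeding with isotropic random directions: the
        # span of K observed maps can miss the global basin on small peak sets
        if r % 2 == 0:
            idx = rng.choice(T, size=K, replace=False)
            A = V[idx].copy()
        else:
            A = rng.standard_normal((K, C))
        A = A - A.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(A, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        A /= norms
        prev_s2 = np.inf
        labels = np.zeros(T, dtype=np.int64)
        for _ in range(max_iter):
            proj = V @ A.T  # T x K
            labels = np.argmax(proj**2, axis=1)
            resid = sq_norm - proj[np.arange(T), labels] ** 2
            # re-seed empty clusters from the worst-fit map
            for k in range(K):
                if not np.any(labels == k):
                    worst = int(np.argmax(resid))
                    labels[worst] = k
                    resid[worst] = 0.0
            for k in range(K):
                members = V[labels == k]
                A[k] = _principal_direction(members, init=A[k])
            proj = np.einsum("tc,tc->t", V, A[labels])
            s2 = float(max((sq_norm - proj**2).sum(), 0.0) / denom)
            if prev_s2 < np.inf and abs(prev_s2 - s2) <= tol * max(prev_s2, 1e-300):
                converged[r] = True
                prev_s2 = s2
                break
            prev_s2 = s2
        s2 = prev_s2 if np.isfinite(prev_s2) else _sigma2(V, A, labels)
        if best is None or s2 < best[0]:
            best = (s2, A.copy(), labels.copy())

    s2, A, labels = best
    # final assignment consistent with returned prototypes (lowest-index ties)
    proj = V @ A.T
    labels = np.argmax(proj**2, axis=1)
    s2 = _sigma2(V, A, labels)
    A = _canonical_sign(A)
    prototypes = PrototypeSet(maps=A)
    gev = compute_gev(peaks.maps, prototypes, labels)[1]
    cv = compute_cv_criterion(s2, C, K) if C - 1 > K else float("nan")
    return SegmentationFit(
        prototypes=prototypes,
        labels=labels,
        sigma2_hat=s2,
        gev=gev,
        cv=cv,
        n_restarts_used=n_restarts,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Fit criteria
# ---------------------------------------------------------------------------

def compute_gev(
    maps: np.ndarray,
    prototypes: PrototypeSet,
    labels: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Global explained variance, per class and total.

    GEV_total = Σ_t (GFP_t · r_t)² / Σ_t GFP_t², with r_t the spatial
    correlation between map t and its assigned prototype; per-class terms
    restrict the numerator to that class, so they sum to the total.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    labels = np.asarray(labels, dtype=np.int64)
    centered = maps - maps.mean(axis=1, keepdims=True)
    C = maps.shape[1]
    gfp = np.sqrt(np.mean(centered**2, axis=1))
    total = float((gfp**2).sum())
    if total == 0:
        raise ValidationError("zero total GFP; cannot compute GEV")
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    corr = np.einsum("tc,tc->t", centered / safe[:, None], prototypes.maps[labels])
    corr[norms == 0] = 0.0
    contrib = (gfp * corr) ** 2
    K = prototypes.K
    per_class = np.array([contrib[labels == k].sum() for k in range(K)]) / total
    return per_class, float(per_class.sum())


def compute_cv_criterion(sigma2_hat: float, C: int, K: int) -> float:
    """Predictive residual-variance criterion: CV = σ̂² ((C−1)/(C−1−K))²."""
    if C - 1 <= K:
        raise ValidationError(f"CV undefined for C={C}, K={K} (need C-1 > K)")
    return float(sigma2_hat * ((C - 1) / (C - 1 - K)) ** 2)


def scan_k(
    peaks: PeakSet,
    k_range: Sequence[int] = tuple(range(2, 9)),
    n_restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-7,
    seed: int = 0,
) -> dict[int, SegmentationFit]:
    """Fit the modified k-means at every K in ``k_range`` (default 2–8).

    Passing a single-element range reproduces a forced fixed-K solution,
    e.g. the four-class sensitivity mode.
    """
    k_range = list(k_range)
    if any(k < 2 or k >= peaks.n_peaks for k in k_range):
        raise ValidationError(f"k_range {k_range} outside [2, n_peaks)")
    fits: dict[int, SegmentationFit] = {}
    for i, k in enumerate(k_range):
        fits[k] = modified_kmeans(
            peaks, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=seed + 1000 * i,
        )
    return fits
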