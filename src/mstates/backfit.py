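"""Backfitting, temporal smoothing, microstate statistics and outlier trimming.

Once prototypes are fixed, every EEG sample is labeled with the prototype
of maximal absolute spatial correlation (polarity-invariant).  Brief
spurious segments — a known artifact of sample-wise labeling under noise —
are reassigned to the next-best-fitting class by global map dissimilarity
until no within-epoch run is shorter than the smoothing threshold.  From
the smoothed labels four per-class statistics are computed: mean duration
(ms), occurrence rate (/s), time coverage (fraction) and global explained
variance.  Found prototypes can be matched one-to-one to a reference set
(or to idealized canonical templates A–G) by Hungarian assignment on
absolute spatial correlation, and feature tables are trimmed of per-group
±z·SD outliers before trajectory modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_ingest import EpochedEEG, FeatureTable, ValidationError
from .segmentation import GFPSeries, PrototypeSet, compute_gev

logger = logging.getLogger("mstates")

__all__ = [
    "LabelSequence",
    "MicrostateStats",
    "ClassMapping",
    "backfit_labels",
    "smooth_short_segments",
    "compute_microstate_stats",
    "match_prototypes",
    "canonical_templates",
    "trim_feature_outliers",
]

CANONICAL_LABELS = ("A", "B", "C", "D", "E", "F", "G")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LabelSequence:
    """Per-sample microstate labels with the full |correlation| matrix.

    ``labels`` is (n_epochs, n_samples); ``corr`` is
    (n_epochs, n_samples, K) absolute spatial correlations with every
    prototype, retained so smoothing can fall back to next-best classes.
    """

    labels: np.ndarray
    corr: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.corr = np.asarray(self.corr, dtype=float)
        K = self.corr.shape[-1]
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= K:
            raise ValidationError("labels out of range [0, K)")
        if self.corr.min(initial=0.0) < -1e-9 or self.corr.max(initial=0.0) > 1 + 1e-9:
            raise ValidationError("correlations out of [0, 1]")

    @property
    def K(self) -> int:
        return self.corr.shape[-1]


@dataclass
class MicrostateStats:
    """Per-class temporal statistics of a labeled recording."""

    duration_ms: np.ndarray  # NaN where a class never occurs
    occurrence_per_s: np.ndarray
    coverage_fraction: np.ndarray
    gev: np.ndarray
    retained_segments: int

    def as_records(self) -> list[dict]:
        out = []
        for k in range(len(self.duration_ms)):
            out.append({
                "class_index": k,
                "duration": float(self.duration_ms[k]),
                "occurrence": float(self.occurrence_per_s[k]),
                "coverage": float(self.coverage_fraction[k]),
                "gev": float(self.gev[k]),
            })
        return out


@dataclass
class ClassMapping:
    """One-to-one assignment of found maps to reference/canonical labels."""

    assignment: dict[int, str]  # found-map index -> label (or "unclassified")
    scores: dict[int, float]  # matched |spatial correlation|


# ---------------------------------------------------------------------------
# Backfitting
# ---------------------------------------------------------------------------

def _abs_corr_matrix(epochs: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    centered = epochs - epochs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe
    corr = np.abs(np.einsum("ecs,kc->esk", unit, prototypes))
    corr[np.squeeze(norms, axis=1) == 0] = 0.0
    return np.clip(corr, 0.0, 1.0)


def backfit_labels(ep: EpochedEEG, prototypes: PrototypeSet) -> LabelSequence:
    """Label every sample with the prototype of maximal |spatial correlation|.

    Polarity- and scale-invariant.  Ties (including all-zero samples) break
    to the lowest class index; the per-sample correlation matrix is kept for
    later smoothing.
    """
    if ep.n_channels != prototypes.n_channels:
        raise ValidationError(
            f"epochs have {ep.n_channels} channels, prototypes {prototypes.n_channels}"
        )
    corr = _abs_corr_matrix(ep.epochs, prototypes.maps)
    labels = np.argmax(corr, axis=-1)
    return LabelSequence(labels=labels, corr=corr, fs=ep.fs)


# ---------------------------------------------------------------------------
# Temporal smoothing
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, length, label) runs of a 1-D label vector."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e - s), int(labels[s])) for s, e in zip(starts, ends)]


def _smooth_epoch(labels: np.ndarray, corr: np.ndarray, thr: int) -> np.ndarray:
    """Reassign sub-threshold runs to next-best classes until none remain.

    Shortest run first (ties: earliest).  Each sample of a rejected run
    excludes its current label from future consideration and takes the
    highest-|corr| label not yet rejected for it; when a sample has
    exhausted every label, the run is merged into the neighboring run with
    the higher boundary correlation.  A run spanning the whole epoch is
    left alone (nothing shorter than the epoch can fix it).
    """
    labels = labels.copy()
    n, K = corr.shape
    rejected = np.zeros((n, K), dtype=bool)
    max_steps = n * (K + 2) + 10  # safety cap; rejections grow monotonically
    for _ in range(max_steps):
        runs = _runs(labels)
        short = [r for r in runs if r[1] < thr and r[1] < n]
        if not short:
            return labels
        start, length, lab = min(short, key=lambda r: (r[1], r[0]))
        sl = slice(start, start + length)
        rejected[sl, lab] = True
        exhausted = rejected[sl].all(axis=1)
        if exhausted.any():
            # merge into the neighbor with the higher boundary correlation
            left_lab = labels[start - 1] if start > 0 else None
            right_lab = labels[start + length] if start + length < n else None
            if left_lab is None and right_lab is None:  # pragma: no cover
                return labels
            if left_lab is None:
                new = right_lab
            elif right_lab is None:
                new = left_lab
            else:
                new = left_lab if corr[start, left_lab] >= corr[start + length - 1, right_lab] \
                    else right_lab
            labels[sl] = new
            continue
        masked = np.where(rejected[sl], -np.inf, corr[sl])
        labels[sl] = np.argmax(masked, axis=1)
    return labels  # pragma: no cover - cap reached


def smooth_short_segments(seq: LabelSequence, min_duration_ms: float = 30.0) -> LabelSequence:
    """Reject within-epoch label runs shorter than ``min_duration_ms``.

    Rejected samples are reassigned to the next best-fitting microstate by
    global map dissimilarity, GMD = sqrt(2 (1 − |corr|)), which for the
    stored absolute correlations is the same ordering as next-highest
    |corr|.  Epochs are processed independently; the default 30 ms matches
    standard microstate practice.
    """
    thr = int(np.ceil(min_duration_ms * seq.fs / 1000.0 - 1e-9))
    if thr <= 1:
        return LabelSequence(labels=seq.labels.copy(), corr=seq.corr, fs=seq.fs)
    out = seq.labels.copy()
    for e in range(out.shape[0]):
        out[e] = _smooth_epoch(out[e], seq.corr[e], thr)
    return LabelSequence(labels=out, corr=seq.corr, fs=seq.fs)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def compute_microstate_stats(
    seq: LabelSequence,
    gfp: GFPSeries | None = None,
    prototypes: PrototypeSet | None = None,
    epochs: np.ndarray | None = None,
) -> MicrostateStats:
    """Duration, occurrence, coverage and (optionally) GEV per class.

    Runs are counted within epochs only — epochs are discontinuous excerpts
    of the recording, so a label run never spans an epoch boundary, and
    boundary-truncated runs are counted like any other.  Under that
    convention the identity

        occurrence_k × duration_k / 1000 = coverage_k

    holds exactly for every class present.  Duration is the mean run length
    in ms; occurrence is runs per second of labeled data; coverage is the
    fraction of samples.  GEV per class is computed over all samples when
    ``prototypes`` and ``epochs`` are given.
    """
    K = seq.K
    n_epochs, n_samples = seq.labels.shape
    total_samples = n_epochs * n_samples
    if total_samples == 0:
        raise ValidationError("empty label sequence")
    total_s = total_samples / seq.fs
    run_counts = np.zeros(K)
    run_samples = np.zeros(K)
    for e in range(n_epochs):
        for _, length, lab in _runs(seq.labels[e]):
            run_counts[lab] += 1
            run_samples[lab] += length
    with np.errstate(invalid="ignore", divide="ignore"):
        duration_ms = np.where(
            run_counts > 0, run_samples / run_counts * 1000.0 / seq.fs, np.nan
        )
    occurrence = run_counts / total_s
    coverage = run_samples / total_samples
    gev = np.full(K, np.nan)
    if prototypes is not None and epochs is not None:
        flat = epochs.transpose(0, 2, 1).reshape(-1, epochs.shape[1])
        gev = compute_gev(flat, prototypes, seq.labels.reshape(-1))[0]
    return MicrostateStats(
        duration_ms=duration_ms,
        occurrence_per_s=occurrence,
        coverage_fraction=coverage,
        gev=gev,
        retained_segments=n_epochs,
    )


# ---------------------------------------------------------------------------
# Canonical templates and map matching
# ---------------------------------------------------------------------------

#: Idealized dipole orientations (x = right, y = anterior, z = up) behind the
#: canonical microstate families: A right-frontal→left-posterior, B its mirror,
#: C anterior–posterior, D fronto-central→occipital (steeper), E centro-parietal
#: radial, F/G left/right lateralized.  These are synthetic idealizations for
#: automated matching, standing in for visual classification.
_CANONICAL_ORIENTATIONS = {
    "A": (0.707, 0.707, 0.0),
    "B": (-0.707, 0.707, 0.0),
    "C": (0.0, 1.0, 0.0),
    "D": (0.0, 0.555, 0.832),
    "E": (0.0, -0.287, 0.958),
    "F": (-0.958, 0.0, 0.287),
    "G": (0.958, 0.0, 0.287),
}


def canonical_templates(positions: np.ndarray) -> PrototypeSet:
    """Idealized canonical A–G template maps rendered on a montage."""
    positions = np.asarray(positions, dtype=float)
    maps = []
    for lab in CANONICAL_LABELS:
        m = positions @ np.array(_CANONICAL_ORIENTATIONS[lab])
        m = m - m.mean()
        maps.append(m / np.linalg.norm(m))
    return PrototypeSet(maps=np.array(maps), channel_names=[])


def match_prototypes(
    found: PrototypeSet,
    reference: PrototypeSet,
    reference_labels: Sequence[str] | None = None,
) -> ClassMapping:
    """Optimal one-to-one map matching by absolute spatial correlation.

    Hungarian assignment on cost 1 − |corr| maximizes the summed matched
    |correlation|; when the reference has fewer maps than were found, the
    leftovers are labeled ``"unclassified"``.  Polarity-invariant.
    """
    if found.n_channels != reference.n_channels:
        raise ValidationError("channel count mismatch between map sets")
    if reference_labels is None:
        reference_labels = [CANONICAL_LABELS[i] if i < len(CANONICAL_LABELS) else str(i)
                            for i in range(reference.K)]
    corr = np.abs(found.maps @ reference.maps.T)
    rows, cols = linear_sum_assignment(1.0 - corr)
    assignment = {int(i): "unclassified" for i in range(found.K)}
    scores = {int(i): 0.0 for i in range(found.K)}
    for i, j in zip(rows, cols):
        assignment[int(i)] = str(reference_labels[j])
        scores[int(i)] = float(corr[i, j])
    return ClassMapping(assignment=assignment, scores=scores)


# ---------------------------------------------------------------------------
# Outlier trimming
# ---------------------------------------------------------------------------

def trim_feature_outliers(
    table: FeatureTable, z: float = 3.0
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove per-group ±z·SD outliers from a feature table.

    Groups are (cohort, visit, class, feature); within each, values with
    |value − mean| > z·SD are dropped (mean and SD computed on the full
    group including the candidate; sample SD).  Only the offending value is
    removed, not the whole subject-visit record.  Constant groups (SD = 0)
    remove nothing; groups of fewer than 3 values are skipped with a
    warning.  Returns the trimmed table and a per-group removal report.
    """
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    report_rows = []
    for key, grp in df.groupby(["cohort", "visit", "class", "feature"], sort=True):
        if len(grp) < 3:
            logger.warning("outlier trim: group %s has %d values; skipped", key, len(grp))
            continue
        vals = grp["value"].astype(float)
        mean, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            n_removed = 0
        else:
            bad = (vals - mean).abs() > z * sd
            keep[grp.index[bad]] = False
            n_removed = int(bad.sum())
        report_rows.append({
            "cohort": key[0], "visit": key[1], "class": key[2], "feature": key[3],
            "n": len(grp), "n_removed": n_removed,
        })
    report = pd.DataFrame(
        report_rows,
        columns=["cohort", "visit", "class", "feature", "n", "n_removed"],
    )
    return FeatureTable(df[keep].reset_index(drop=True)), report
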