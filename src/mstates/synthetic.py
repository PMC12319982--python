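"""Synthetic EEG with planted microstate structure and longitudinal tables.

Every downstream stage of the pipeline is exercised against data generated
here, where the ground truth — prototype maps, state labels, dwell times,
fixed effects, variance components — is known exactly.

The EEG generator plants a semi-Markov state sequence (geometric dwell
times, no self-transitions) whose active prototype map is scaled by a
rectified-sinusoid envelope, mimicking the alternating-polarity generator
picture in which topographies recur at global field power peaks every
oscillatory half-cycle.  Sensor noise is spatially white Gaussian, scaled
to a requested signal-to-noise ratio (RMS of the noiseless state signal
over RMS of the noise, both after average referencing).

The longitudinal generator draws subject random intercepts and Gaussian
residuals around a fixed-effect surface in age (linear plus optionally
quadratic or logarithmic), sex and retained-segment count; default visit
ages follow the four-visit infancy schedule (means 3.74, 8.72, 14.1 and
21.5 months) of the cohorts this package models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io_ingest import EpochedEEG, FeatureTable, ValidationError

__all__ = [
    "GroundTruth",
    "LongitudinalTruth",
    "make_montage",
    "make_prototype_maps",
    "simulate_state_sequence",
    "simulate_microstate_eeg",
    "simulate_longitudinal_features",
]

#: Default four-visit age schedule: (mean, SD) in months per visit.
DEFAULT_VISIT_AGES: tuple[tuple[float, float], ...] = (
    (3.74, 0.879),
    (8.72, 1.49),
    (14.1, 1.24),
    (21.5, 1.20),
)


@dataclass
class GroundTruth:
    """What was planted in a synthetic EEG recording."""

    prototypes: "object"  # segmentation.PrototypeSet; kept loose to avoid cycle
    labels: np.ndarray  # per-sample true state, flat over the whole recording
    mean_durations_ms: np.ndarray
    snr: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        runs = _run_length_encode(self.labels)
        payload = {
            "prototype_maps": np.asarray(self.prototypes.maps).tolist(),
            "labels_rle": runs,
            "mean_durations_ms": np.asarray(self.mean_durations_ms).tolist(),
            "snr": None if np.isinf(self.snr) else float(self.snr),
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(payload))


@dataclass
class LongitudinalTruth:
    """Generating parameters for a longitudinal feature table.

    ``beta`` holds the fixed effects in order (intercept, age, nonlinear-age,
    sex, segments); the nonlinear entry is ignored for the linear age model.
    ``sigma_u`` is the between-subject (random-intercept) SD, ``sigma_e``
    the residual SD, in the units of the simulated feature.
    """

    beta: tuple[float, float, float, float, float]
    sigma_u: float
    sigma_e: float
    n_subjects: int
    visit_ages: Sequence[tuple[float, float]] = DEFAULT_VISIT_AGES
    missing_rate: float = 0.0
    segments_mean: float = 55.0
    segments_sd: float = 18.0
    segments_range: tuple[int, int] = (16, 91)

    def __post_init__(self) -> None:
        if self.sigma_u < 0:
            raise ValidationError("sigma_u must be >= 0")
        if self.sigma_e <= 0:
            raise ValidationError("sigma_e must be > 0")
        if any(m <= 0 for m, _ in self.visit_ages):
            raise ValidationError("visit age means must be positive")


def _run_length_encode(labels: np.ndarray) -> list[list[int]]:
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# Montage and prototype maps
# ---------------------------------------------------------------------------

def make_montage(n_channels: int, seed: int = 0) -> np.ndarray:
    """Near-uniform unit-sphere sensor positions, biased to the upper head.

    A golden-spiral lattice over the spherical cap z > -0.35 (electrodes do
    not cover the underside of the head) with a small seeded jitter, then
    re-normalized.  Deterministic for a given (n_channels, seed).
    """
    if n_channels < 4:
        raise ValidationError("need at least 4 channels")
    rng = np.random.default_rng(seed)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_channels)
    z = 1.0 - (1.0 + 0.35) * (i + 0.5) / n_channels  # in (-0.35, 1)
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    theta = golden * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts = pts + rng.normal(scale=0.01, size=pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_prototype_maps(
    positions: np.ndarray,
    K: int,
    seed: int = 0,
    max_abs_corr: float = 0.7,
    max_draws: int = 2000,
):
    """Draw K smooth dipolar prototype topographies on a montage.

    Each map is the dot product of the channel positions with a random
    orientation — a rank-1 linear field, the idealized far-field pattern of
    a single equivalent dipole.  Maps are channel-demeaned and unit-normed;
    orientations are rejection-sampled until every pair of maps satisfies
    |spatial correlation| <= ``max_abs_corr``.
    """
    from .segmentation import PrototypeSet, spatial_correlation

    if K < 2:
        raise ValidationError("need K >= 2 prototype maps")
    positions = np.asarray(positions, dtype=float)
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    draws = 0
    misses = 0  # consecutive rejections; a stuck greedy set is restarted
    while len(maps) < K:
        if draws >= max_draws:
            raise ValidationError(
                f"could not find {K} maps with pairwise |corr| <= {max_abs_corr} "
                f"in {max_draws} draws; try a larger montage or looser bound"
            )
        draws += 1
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        m = positions @ u
        m = m - m.mean()
        norm = np.linalg.norm(m)
        if norm < 1e-12:
            continue
        m /= norm
        if all(abs(spatial_correlation(m, prev)) <= max_abs_corr for prev in maps):
            maps.append(m)
            misses = 0
        else:
            misses += 1
            if misses >= 200:
                maps.clear()
                misses = 0
    return PrototypeSet(maps=np.array(maps))


# ---------------------------------------------------------------------------
# State sequences and EEG
# ---------------------------------------------------------------------------

def simulate_state_sequence(
    K: int,
    mean_durations_ms: float | Sequence[float],
    fs: float,
    n_samples: int,
    seed: int = 0,
) -> np.ndarray:
    """Semi-Markov microstate label sequence.

    Dwell times are geometric (memoryless) with the stated per-state mean;
    on leaving a state the next one is uniform over the other K - 1 states,
    so consecutive runs never share a label.  ``K = 1`` degenerates to a
    constant sequence.
    """
    means = np.broadcast_to(np.asarray(mean_durations_ms, dtype=float), (K,)).copy()
    if np.any(means <= 0):
        raise ValidationError("mean durations must be positive")
    mean_samples = means * fs / 1000.0
    if np.any(mean_samples < 2):
        raise ValidationError("mean durations must be at least 2 samples")
    if K == 1:
        return np.zeros(n_samples, dtype=np.int64)
    rng = np.random.default_rng(seed)
    labels = np.empty(n_samples, dtype=np.int64)
    state = int(rng.integers(K))
    t = 0
    while t < n_samples:
        dwell = int(rng.geometric(1.0 / mean_samples[state]))
        end = min(t + dwell, n_samples)
        labels[t:end] = state
        t = end
        nxt = int(rng.integers(K - 1))
        state = nxt + (nxt >= state)
    return labels


def simulate_microstate_eeg(
    prototypes,
    labels: np.ndarray,
    fs: float,
    snr: float = 4.0,
    env_freq_hz: float = 10.0,
    amplitude_uv: float = 15.0,
    epoch_length_s: float = 2.0,
    seed: int = 0,
    mean_durations_ms: float | Sequence[float] | None = None,
) -> tuple[EpochedEEG, GroundTruth]:
    """Render a label sequence into epoched EEG.

    Sample ``t`` is ``amplitude * |sin(2π f t / fs)| * map[label(t)]`` plus
    spatially white Gaussian noise, average-referenced and scaled so that
    RMS(signal) / RMS(noise) equals ``snr``.  ``snr = inf`` disables noise.
    Envelope maxima every half-cycle create the GFP peaks the segmentation
    stage feeds on.
    """
    if not (snr > 0):
        raise ValidationError("snr must be positive (use np.inf for noise-free)")
    labels = np.asarray(labels, dtype=np.int64)
    maps = np.asarray(prototypes.maps, dtype=float)
    n_per = int(round(fs * epoch_length_s))
    if labels.size % n_per != 0:
        raise ValidationError(
            f"label sequence of {labels.size} samples does not divide into "
            f"{epoch_length_s} s epochs of {n_per} samples"
        )
    t = np.arange(labels.size) / fs
    envelope = amplitude_uv * np.abs(np.sin(2 * np.pi * env_freq_hz * t))
    signal = envelope[:, None] * maps[labels]  # samples x channels
    rng = np.random.default_rng(seed)
    if np.isinf(snr):
        noise = np.zeros_like(signal)
    else:
        noise = rng.standard_normal(signal.shape)
        noise -= noise.mean(axis=1, keepdims=True)  # average-reference the noise
        sig_rms = np.sqrt(np.mean(signal**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        noise *= sig_rms / (snr * noise_rms)
    data = (signal + noise).T  # channels x samples
    n_epochs = labels.size // n_per
    n_channels = maps.shape[1]
    epochs = data.reshape(n_channels, n_epochs, n_per).transpose(1, 0, 2)
    positions = make_montage(n_channels, seed=0)
    ep = EpochedEEG(
        epochs=epochs.copy(),
        fs=fs,
        epoch_length_s=epoch_length_s,
        channel_positions=positions,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        reference="average",
    )
    if mean_durations_ms is None:
        planted = np.full(maps.shape[0], np.nan)
    else:
        planted = np.broadcast_to(
            np.asarray(mean_durations_ms, dtype=float), (maps.shape[0],)
        ).copy()
    truth = GroundTruth(
        prototypes=prototypes,
        labels=labels,
        mean_durations_ms=planted,
        snr=snr,
        seed=seed,
    )
    return ep, truth


# ---------------------------------------------------------------------------
# Longitudinal feature tables
# ---------------------------------------------------------------------------

def _age_term(age: np.ndarray, age_model: str) -> np.ndarray:
    if age_model == "linear":
        return np.zeros_like(age)
    if age_model == "quadratic":
        return age**2
    if age_model == "log":
        return np.log(age)
    raise ValidationError(f"unknown age model {age_model!r}")


def simulate_longitudinal_features(
    truth: LongitudinalTruth,
    age_model: Literal["linear", "quadratic", "log"],
    seed: int = 0,
    cohort: str = "synthetic",
    class_label: str = "A",
    feature: str = "duration",
) -> tuple[FeatureTable, np.ndarray]:
    """Draw a longitudinal feature table from a random-intercept model.

    y_ij = b0 + b1*age_ij + b2*g(age_ij) + b3*sex_i + b4*segments_ij
           + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

    with g the quadratic or natural-log age term (absent for the linear
    model).  Visit ages are Gaussian per the per-visit (mean, SD) schedule,
    truncated positive; retained-segment counts are rounded truncated
    Gaussians; observations are dropped independently at ``missing_rate``.
    Returns the table and the per-subject intercepts u_i.
    """
    _age_term(np.array([1.0]), age_model)  # validate tag early
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3, b4 = truth.beta
    n, v = truth.n_subjects, len(truth.visit_ages)
    u = rng.normal(0.0, truth.sigma_u, size=n)
    sex = rng.integers(0, 2, size=n)
    rows = []
    for i in range(n):
        for j, (mu, sd) in enumerate(truth.visit_ages):
            if truth.missing_rate > 0 and rng.random() < truth.missing_rate:
                continue
            age = rng.normal(mu, sd)
            while age <= 0.25:  # resample implausible (non-positive) ages
                age = rng.normal(mu, sd)
            seg = int(np.clip(
                round(rng.normal(truth.segments_mean, truth.segments_sd)),
                *truth.segments_range,
            ))
            g = float(_age_term(np.array([age]), age_model)[0]) if age_model != "linear" else 0.0
            y = b0 + b1 * age + (b2 * g if age_model != "linear" else 0.0) \
                + b3 * sex[i] + b4 * seg + u[i] + rng.normal(0.0, truth.sigma_e)
            rows.append(
                dict(
                    subject=f"s{i:04d}",
                    cohort=cohort,
                    visit=j + 1,
                    age_months=age,
                    sex=int(sex[i]),
                    retained_segments=seg,
                    **{"class": class_label},
                    feature=feature,
                    value=y,
                )
            )
    import pandas as pd

    return FeatureTable(pd.DataFrame(rows)), u
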