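"""End-to-end orchestration: config, staging, provenance and logging.

A single YAML-serializable config drives the whole chain

    ingest (or simulate) -> clean -> per-visit segmentation -> backfit
    -> smooth -> statistics -> outlier trim -> trajectory models

writing every artifact (feature table, prototype sets, K-scan summaries,
model tables, structured log) into a run directory stamped with the config
hash and seed, so a rerun with the same config and seed is byte-identical
on all numeric outputs.

Segmentation is performed for each visit separately (prototype identity can
change over development); a shared-template mode across visits is available
for comparability studies but is not the default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backfit as bf
from . import segmentation as seg
from . import synthetic as syn
from . import trajectories as traj
from .io_ingest import (
    EpochedEEG,
    FeatureTable,
    ValidationError,
    apply_average_reference,
    check_retention,
    epoch_recording,
    persist_features,
    read_eeg,
    reject_high_amplitude,
)

logger = logging.getLogger("mstates")

__all__ = ["PipelineConfig", "SimulationBlock", "run_pipeline", "load_config"]


@dataclass
class SimulationBlock:
    """Synthetic-cohort settings; one EEG recording per subject-visit."""

    n_subjects: int = 6
    n_visits: int = 2
    fs: float = 500.0
    n_channels: int = 32
    K: int = 5
    snr: float = 4.0
    mean_duration_ms: float = 80.0
    amplitude_uv: float = 15.0
    env_freq_hz: float = 10.0
    min_epochs: int = 17  # recording lengths vary per subject-visit
    max_epochs: int = 25


@dataclass
class PipelineConfig:
    cohort: str = "synthetic"
    inputs: list[dict] = field(default_factory=list)  # ingest mode records
    simulate: SimulationBlock | None = field(default_factory=SimulationBlock)
    epoch_length_s: float = 2.0
    amplitude_threshold_uv: float = 150.0
    min_segments: int = 15
    n_peaks: int = 1000
    min_peak_distance_ms: float = 10.0
    k_min: int = 2
    k_max: int = 8
    forced_k: int | None = None
    n_restarts: int = 50
    max_iter: int = 1000
    smoothing_ms: float = 30.0
    outlier_z: float = 3.0
    model_features: list[str] = field(default_factory=lambda: ["duration", "occurrence"])
    fit_models: bool = True
    shared_template: bool = False  # non-default: one prototype set for all visits
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SimulationBlock(**self.simulate)
        for name in ("epoch_length_s", "amplitude_threshold_uv", "n_peaks",
                     "min_peak_distance_ms", "smoothing_ms", "outlier_z"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.simulate is None and not self.inputs:
            raise ValidationError("config needs either a simulate block or inputs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (missing keys take defaults)."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**payload)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def clean_epochs(ep: EpochedEEG, cfg: PipelineConfig) -> EpochedEEG | None:
    """Amplitude rejection, average reference and the retention gate."""
    ep, removed = reject_high_amplitude(ep, cfg.amplitude_threshold_uv)
    if removed:
        logger.info("rejected %d high-amplitude epochs", len(removed))
    ep = apply_average_reference(ep)
    decision = check_retention(ep, cfg.min_segments)
    if not decision.passed:
        logger.warning("retention gate failed: %d epochs <= %d",
                       decision.n_epochs, decision.min_segments)
        return None
    return ep


def _simulate_subject_visit(cfg: PipelineConfig, subject: int, visit: int,
                            prototypes, rng: np.random.Generator) -> EpochedEEG:
    sim = cfg.simulate
    n_epochs = int(rng.integers(sim.min_epochs, sim.max_epochs + 1))
    n_samples = n_epochs * int(round(sim.fs * cfg.epoch_length_s))
    sseed = int(rng.integers(2**31 - 1))
    labels = syn.simulate_state_sequence(
        sim.K, sim.mean_duration_ms, sim.fs, n_samples, seed=sseed)
    ep, _ = syn.simulate_microstate_eeg(
        prototypes, labels, sim.fs, snr=sim.snr, env_freq_hz=sim.env_freq_hz,
        amplitude_uv=sim.amplitude_uv, epoch_length_s=cfg.epoch_length_s,
        seed=sseed + 1)
    return ep


def segment_visit(pooled: seg.PeakSet, cfg: PipelineConfig, seed: int
                  ) -> tuple[seg.SegmentationFit, pd.DataFrame]:
    """Cluster pooled per-visit peaks; forced K or CV-selected from a scan."""
    if cfg.forced_k is not None:
        fits = {cfg.forced_k: seg.modified_kmeans(
            pooled, cfg.forced_k, n_restarts=cfg.n_restarts,
            max_iter=cfg.max_iter, seed=seed)}
        chosen = cfg.forced_k
    else:
        fits = seg.scan_k(pooled, range(cfg.k_min, cfg.k_max + 1),
                          n_restarts=cfg.n_restarts, max_iter=cfg.max_iter,
                          seed=seed)
        chosen = min(fits, key=lambda k: fits[k].cv)
    summary = pd.DataFrame(
        [{"K": k, "sigma2_hat": f.sigma2_hat, "gev": f.gev, "cv": f.cv,
          "selected": int(k == chosen)} for k, f in sorted(fits.items())]
    )
    return fits[chosen], summary


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write artifacts to ``out_dir``.

    Outputs: ``features.csv`` (long-format table, post-trim),
    ``features_raw.csv`` (pre-trim), ``prototypes_visit<j>.json``,
    ``kscan_visit<j>.csv``, ``models.csv`` + ``models.json`` (when
    modeling is enabled), ``provenance.json`` and ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path) -> Path:
    master = np.random.SeedSequence(cfg.seed)
    (out / "provenance.json").write_text(json.dumps({
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }, indent=2, sort_keys=True))

    # ---- ingest or simulate ------------------------------------------------
    # records: (subject, visit, age_months, sex, EpochedEEG)
    records: list[tuple[str, int, float, int, EpochedEEG]] = []
    if cfg.simulate is not None:
        sim = cfg.simulate
        proto_seed, subj_seed, age_seed = (
            int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(3))
        positions = syn.make_montage(sim.n_channels, seed=0)
        planted = syn.make_prototype_maps(positions, sim.K, seed=proto_seed,
                                          max_abs_corr=0.6)
        rng = np.random.default_rng(subj_seed)
        age_rng = np.random.default_rng(age_seed)
        schedule = syn.DEFAULT_VISIT_AGES[: sim.n_visits]
        for i in range(sim.n_subjects):
            sex = int(rng.integers(0, 2))
            for j, (mu, sd) in enumerate(schedule):
                age = float(max(0.5, age_rng.normal(mu, sd)))
                ep = _simulate_subject_visit(cfg, i, j, planted, rng)
                records.append((f"s{i:03d}", j + 1, age, sex, ep))
        logger.info("simulated %d subject-visits", len(records))
    else:
        for rec in cfg.inputs:
            raw = read_eeg(rec["path"], rec.get("format"))
            ep = epoch_recording(raw, cfg.epoch_length_s)
            records.append((str(rec["subject"]), int(rec.get("visit", 1)),
                            float(rec["age_months"]), int(rec.get("sex", 0)), ep))
        logger.info("ingested %d recordings", len(records))

    # ---- clean -------------------------------------------------------------
    cleaned = []
    for subject, visit, age, sex, ep in records:
        ep2 = clean_epochs(ep, cfg)
        if ep2 is None:
            logger.warning("dropping %s visit %d (retention gate)", subject, visit)
            continue
        cleaned.append((subject, visit, age, sex, ep2))
    if not cleaned:
        raise ValidationError("no subject-visit passed cleaning")

    # ---- per-visit segmentation ---------------------------------------------
    visits = sorted({v for _, v, *_ in cleaned})
    seg_seeds = {v: int(s.generate_state(1)[0] % (2**31 - 1))
                 for v, s in zip(visits, master.spawn(len(visits)))}
    peak_seed_rng = np.random.default_rng(
        int(master.spawn(1)[0].generate_state(1)[0] % (2**31 - 1)))
    visit_fits: dict[int, seg.SegmentationFit] = {}
    visit_peaks: dict[int, list[seg.PeakSet]] = {v: [] for v in visits}
    for subject, visit, age, sex, ep in cleaned:
        gfp = seg.compute_gfp(ep)
        peaks = seg.pick_gfp_peaks(gfp, ep, cfg.min_peak_distance_ms, cfg.n_peaks,
                                   seed=int(peak_seed_rng.integers(2**31 - 1)))
        visit_peaks[visit].append(peaks)

    def pool(peaksets: list[seg.PeakSet]) -> seg.PeakSet:
        return seg.PeakSet(
            maps=np.vstack([p.maps for p in peaksets]),
            gfp_at_peak=np.concatenate([p.gfp_at_peak for p in peaksets]),
            source=np.vstack([p.source for p in peaksets]),
        )

    if cfg.shared_template:
        pooled_all = pool([p for v in visits for p in visit_peaks[v]])
        fit, summary = segment_visit(pooled_all, cfg, seg_seeds[visits[0]])
        for v in visits:
            visit_fits[v] = fit
        fit.prototypes.to_json(out / "prototypes_shared.json")
        summary.to_csv(out / "kscan_shared.csv", index=False)
    else:
        for v in visits:
            fit, summary = segment_visit(pool(visit_peaks[v]), cfg, seg_seeds[v])
            visit_fits[v] = fit
            fit.prototypes.to_json(out / f"prototypes_visit{v}.json")
            summary.to_csv(out / f"kscan_visit{v}.csv", index=False)
            logger.info("visit %d: K=%d, GEV=%.3f", v, fit.prototypes.K, fit.gev)

    # ---- backfit, smooth, statistics ----------------------------------------
    rows = []
    positions = cleaned[0][4].channel_positions
    templates = bf.canonical_templates(positions)
    mapping_per_visit = {
        v: bf.match_prototypes(visit_fits[v].prototypes, templates)
        for v in visits
    }
    (out / "class_mapping.json").write_text(json.dumps(
        {str(v): {"assignment": {str(k): lab for k, lab in m.assignment.items()},
                  "scores": {str(k): s for k, s in m.scores.items()}}
         for v, m in mapping_per_visit.items()}, indent=2, sort_keys=True))
    for subject, visit, age, sex, ep in cleaned:
        prototypes = visit_fits[visit].prototypes
        labeled = bf.backfit_labels(ep, prototypes)
        smoothed = bf.smooth_short_segments(labeled, cfg.smoothing_ms)
        stats = bf.compute_microstate_stats(
            smoothed, prototypes=prototypes, epochs=ep.epochs)
        mapping = mapping_per_visit[visit].assignment
        for k in range(prototypes.K):
            cls = mapping.get(k, "unclassified")
            for feat, val in (
                ("duration", stats.duration_ms[k]),
                ("occurrence", stats.occurrence_per_s[k]),
                ("coverage", stats.coverage_fraction[k]),
                ("gev", stats.gev[k]),
            ):
                if np.isnan(val):
                    continue
                rows.append(dict(
                    subject=subject, cohort=cfg.cohort, visit=visit,
                    age_months=age, sex=sex,
                    retained_segments=stats.retained_segments,
                    **{"class": cls}, feature=feat, value=float(val),
                ))
    table = FeatureTable(pd.DataFrame(rows))
    persist_features(table, out / "features_raw.csv")

    trimmed, report = bf.trim_feature_outliers(table, cfg.outlier_z)
    report.to_csv(out / "outlier_report.csv", index=False)
    persist_features(trimmed, out / "features.csv")
    logger.info("feature table: %d rows (%d before trimming)",
                len(trimmed), len(table))

    # ---- trajectory models ---------------------------------------------------
    if cfg.fit_models:
        _fit_models(trimmed, cfg, out)
    return out


def _fit_models(table: FeatureTable, cfg: PipelineConfig, out: Path) -> None:
    df = table.df
    n_visits = df["visit"].nunique()
    model_rows = []
    model_json: dict = {}
    for feature in cfg.model_features:
        for cls in sorted(df.loc[df["feature"] == feature, "class"].unique()):
            sub = df[(df["feature"] == feature) & (df["class"] == cls)]
            # model only classes observed at every visit, as for longitudinal
            # trajectories only classes present throughout are comparable
            if sub["visit"].nunique() < n_visits or sub["subject"].nunique() < 3:
                continue
            sub_table = FeatureTable(sub.reset_index(drop=True))
            include_sex = sub["sex"].nunique() > 1
            include_segments = sub["retained_segments"].nunique() > 1
            if not include_sex or not include_segments:
                logger.warning("constant covariate dropped for %s/%s", feature, cls)
            fits = {}
            try:
                for m in traj.AGE_MODELS:
                    spec = traj.ModelSpec(feature=feature, class_label=cls,
                                          age_model=m, include_sex=include_sex,
                                          include_segments=include_segments)
                    fits[m] = traj.fit_random_intercept_lmm(sub_table, spec)
            except ValidationError as exc:
                logger.warning("model skipped for %s/%s: %s", feature, cls, exc)
                continue
            sel = traj.select_age_model(fits)
            best = fits[sel.selected]
            f2 = traj.effect_sizes(sub_table, best)
            for name, row in best.beta.iterrows():
                if name == "intercept":
                    continue
                model_rows.append({
                    "cohort": cfg.cohort, "feature": feature, "class": cls,
                    "age_model": sel.selected, "predictor": name,
                    "estimate": row["estimate"], "se": row["se"], "p": row["p"],
                    "f2": f2.get(name, np.nan),
                    "f2_category": traj.f2_category(f2.get(name, 0.0)),
                })
            model_json[f"{feature}_{cls}"] = {
                "selected": sel.selected,
                "bic": sel.bic,
                "sigma_u2": best.sigma_u2,
                "sigma_e2": best.sigma_e2,
                "loglik": best.loglik,
                "marginal_r2": best.marginal_r2,
                "n_obs": best.n_obs,
            }
    pd.DataFrame(
        model_rows,
        columns=["cohort", "feature", "class", "age_model", "predictor",
                 "estimate", "se", "p", "f2", "f2_category"],
    ).to_csv(out / "models.csv", index=False)
    (out / "models.json").write_text(json.dumps(model_json, indent=2, sort_keys=True))
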