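"""End-to-end orchestration: simulate/load -> QC -> metrics -> DistEn -> models.

A run is described by a :class:`RunConfig` (constructible from a plain
``key: value`` config file), executes deterministically for a fixed seed,
and writes CSV outputs plus a manifest that records every threshold,
parameter, seed and per-stage attrition count.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .beats import detect_rpeaks, rri_from_peaks
from .entropy import EmbeddingConfig, distribution_entropy
from .hrv import hrv_summary
from .qc import QCThresholds, RRIRecord, attrition_counts, cohort_qc, reports_to_frame
from .survival import CoxSpec, fit_cox
from .synth import CohortGenParams, generate_cohort

INPUT_MODES = ("simulate", "ecg_dir", "rri_dir", "cohort_csv")


@dataclass
class RunConfig:
    mode: str = "simulate"
    input_path: str | None = None  # directory or CSV for non-simulate modes
    output_dir: str = "disten_run"
    seed: int = 0
    n_subjects: int = 500  # simulate mode
    tiers: tuple[str, ...] = ("A",)
    fit_models: bool = True
    qc: QCThresholds = field(default_factory=QCThresholds)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ValueError(f"mode must be one of {INPUT_MODES}")
        if self.mode != "simulate" and not self.input_path:
            raise ValueError(f"mode {self.mode!r} requires input_path")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = dio.read_manifest(path)
        kwargs: dict = {}
        simple = {f.name: f.type for f in fields(cls)}
        for key, value in raw.items():
            if "." in key:  # qc.* / embedding.* handled below
                continue
            if key not in simple:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("seed", "n_subjects"):
                kwargs[key] = int(value)
            elif key == "fit_models":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key == "tiers":
                kwargs[key] = tuple(t.strip() for t in value.split(",") if t.strip())
            else:
                kwargs[key] = value
        qc_kwargs = {
            k.split(".", 1)[1]: float(v) for k, v in raw.items() if k.startswith("qc.")
        }
        emb_kwargs = {
            k.split(".", 1)[1]: int(v) for k, v in raw.items() if k.startswith("embedding.")
        }
        kwargs.pop("input_path", None)
        if raw.get("input_path"):
            kwargs["input_path"] = raw["input_path"]
        if qc_kwargs:
            kwargs["qc"] = QCThresholds(**qc_kwargs)
        if emb_kwargs:
            kwargs["embedding"] = EmbeddingConfig(**emb_kwargs)
        return cls(**{k: v for k, v in kwargs.items() if not k.startswith("qc.")})


def _load_records(config: RunConfig) -> tuple[list[RRIRecord], pd.DataFrame | None]:
    """Return (RRI records, covariate/outcome table or None)."""
    if config.mode == "simulate":
        cohort = generate_cohort(
            CohortGenParams(n_subjects=config.n_subjects, seed=config.seed), keep_series=True
        )
        records = [
            RRIRecord(rid, series, pacemaker=bool(pm))
            for rid, series, pm in zip(
                cohort["id"], cohort.attrs["rri_series"], cohort["pacemaker"]
            )
        ]
        return records, cohort
    path = Path(config.input_path)
    if config.mode == "rri_dir":
        records = []
        for f in sorted(path.glob("*.txt")) + sorted(path.glob("*.rri")):
            series, pacemaker = dio.read_rri(f)
            records.append(RRIRecord(f.stem, series, pacemaker))
        return records, None
    if config.mode == "ecg_dir":
        from .synth import ECGRecord

        records = []
        for f in sorted(path.glob("*.csv")):
            samples, rate = dio.read_ecg_csv(f)
            peaks = detect_rpeaks(ECGRecord(samples, rate, f.stem))
            if peaks.indices.size < 2:
                records.append(RRIRecord(f.stem, np.empty(0)))
                continue
            records.append(RRIRecord(f.stem, rri_from_peaks(peaks)))
        return records, None
    cohort = pd.read_csv(path)  # cohort_csv: metrics precomputed
    return [], cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the manifest dictionary.

    Writes (as applicable) ``qc_report.csv``, ``metrics.csv``,
    ``cohort.csv``, ``model_results.csv`` and ``manifest.txt`` into the
    output directory.  A stage failure records completed stages in the
    manifest and re-raises.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "embedding.m": config.embedding.m,
        "embedding.tau": config.embedding.tau,
        "embedding.bins": config.embedding.bins,
        "qc.rri_min": config.qc.rri_min,
        "qc.rri_max": config.qc.rri_max,
        "qc.length_sd_mult": config.qc.length_sd_mult,
        "qc.noise_percentile": config.qc.noise_percentile,
        "stages_completed": "",
    }
    completed: list[str] = []
    try:
        records, cohort = _load_records(config)
        completed.append("load")
        manifest["records_in"] = len(records) if records else (0 if cohort is None else len(cohort))

        metrics_df: pd.DataFrame | None = None
        if records:
            kept, reports, frozen = cohort_qc(records, config.qc)
            completed.append("qc")
            reports_to_frame(reports).to_csv(out / "qc_report.csv", index=False)
            counts = attrition_counts(reports)
            for stage, cnt in counts.items():
                manifest[f"attrition.{stage}"] = cnt
            manifest["qc.frozen.length_mean_s"] = f"{frozen.length_mean_s:.6f}"
            manifest["qc.frozen.length_sd_s"] = f"{frozen.length_sd_s:.6f}"
            manifest["qc.frozen.noise_cutoff"] = f"{frozen.noise_cutoff:.6f}"

            rows = []
            for rec in kept:
                h = hrv_summary(rec.rri)
                d = distribution_entropy(rec.rri, config.embedding)
                rows.append(
                    {
                        "record_id": rec.record_id,
                        "n_beats": rec.n_beats,
                        "disten": d.value,
                        "m": config.embedding.m,
                        "tau": config.embedding.tau,
                        "bins": config.embedding.bins,
                        "bin_min": d.bin_min,
                        "bin_max": d.bin_max,
                        "rhr": h.rhr,
                        "rri_mean": h.mean_rri,
                        "rmssd": h.rmssd,
                        "sdnn": h.sdnn,
                        "pnn5": h.pnn5,
                        "pnn10": h.pnn10,
                        "pnn20": h.pnn20,
                    }
                )
            metrics_df = pd.DataFrame(rows)
            metrics_df.to_csv(out / "metrics.csv", index=False)
            completed.append("metrics")

        if config.mode == "simulate" and metrics_df is not None:
            cohort = cohort.drop(columns=["disten", "rhr", "rri_mean", "rmssd", "sdnn"]).merge(
                metrics_df.rename(columns={"record_id": "id"}), on="id", how="inner"
            )
            cohort.to_csv(out / "cohort.csv", index=False)
            completed.append("cohort")

        if (
            config.fit_models
            and cohort is not None
            and "followup" in cohort.columns
            and int(cohort["event"].sum()) < 10
        ):
            manifest["models_skipped"] = (
                f"only {int(cohort['event'].sum())} events; need >= 10"
            )
        elif config.fit_models and cohort is not None and "followup" in cohort.columns:
            results = []
            for tier in config.tiers:
                res = fit_cox(cohort, CoxSpec(tier=tier))
                results.append(
                    {
                        "tier": tier,
                        "outcome": "all_cause",
                        "hr_per_sd_decrease": res.hr_per_sd_decrease,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "p": res.p_value,
                        "concordance": res.concordance,
                        "ph_global_chi2": res.ph_global_chi2,
                        "ph_p": res.ph_p,
                        "n": res.n,
                        "n_events": res.n_events,
                    }
                )
            pd.DataFrame(results).to_csv(out / "model_results.csv", index=False)
            completed.append("models")
    except Exception:
        manifest["stages_completed"] = ",".join(completed)
        manifest["error"] = traceback.format_exc().strip().splitlines()[-1]
        dio.write_manifest(out / "manifest.txt", manifest)
        raise
    manifest["stages_completed"] = ",".join(completed)
    dio.write_manifest(out / "manifest.txt", manifest)
    return manifest
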