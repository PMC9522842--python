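"""End-to-end orchestration and cohort-level aggregation.

A run executes: clean -> filter -> normalize -> fit (all points) ->
identifiability boxes -> truncated fit -> extrapolation -> extreme-case
envelopes -> aggregation, writing CSV/JSON artifacts and a structured log.
Per-patient failures are logged and skipped; they never abort the cohort.
Re-running with the same config and seed reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import Cohort, clean, filter_cohort, normalize, read_cohort, write_cohort
from .fitting import FitConfig, FitResult, fit_patient, fits_to_table, save_fits_json
from .forecast import (
    Envelope,
    ExtrapolationResult,
    PredictConfig,
    extrapolate,
    extreme_envelope,
    fit_truncated,
    prediction_table,
)
from .identifiability import IdentConfig, boxes_to_table, parameter_box, range_frequency
from .model import ScaleConstants
from .synthetic import SyntheticSpec, generate_cohort, truth_table

__all__ = ["PipelineConfig", "CohortSummary", "aggregate", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """One pipeline run: data source, budgets and analysis settings."""

    data: str | None = None          # cohort CSV; None -> synthetic cohort
    out: str = "kuznefit_out"
    seed: int = 0
    n_synthetic: int = 5             # used only when data is None
    ld_noise_sd: float = 1.0
    min_net: int = 7
    n_starts: int = 3
    max_evals: int = 20_000
    max_time: float = 100.0
    epsilon: float = 0.20
    theta: float = 0.10
    zeta: int = 2
    ident_max_evals: int = 3000
    envelope_max_evals: int = 4000
    identify: bool = True
    predict: bool = True
    time_scale: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class CohortSummary:
    """Grouped goodness-of-fit and forecasting statistics."""

    group: tuple
    n_patients: int
    n_r2_fit_undefined: int
    r2_fit_mean: float | None
    r2_fit_median: float | None
    r2_fit_range: float | None
    r2_ext_mean: float | None = None
    r2_ext_median: float | None = None
    r2_ext_range: float | None = None
    mape_mean: float | None = None


def _r2_stats(values: pd.Series) -> tuple[float | None, float | None, float | None, int]:
    defined = values.dropna()
    n_undef = int(values.isna().sum())
    if defined.empty:
        return None, None, None, n_undef
    return (
        float(defined.mean()),
        float(defined.median()),
        float(defined.max() - defined.min()),
        n_undef,
    )


def aggregate(
    results: pd.DataFrame,
    group_by: Sequence[str] = ("study", "arm"),
) -> pd.DataFrame:
    """Grouped summary of fit/extrapolation R^2 and MAPE.

    ``results`` needs one row per patient with an ``r2_fit`` column and
    optionally ``r2_ext`` and ``mape``.  Patients with undefined R^2 are
    excluded from the R^2 statistics and counted separately.  An overall
    row (group keys "all") is appended.
    """
    if results.empty:
        raise ValueError("no results to aggregate")
    group_by = list(group_by)

    def summarize(key, df: pd.DataFrame) -> dict:
        row: dict = dict(zip(group_by, key)) if group_by else {}
        row["n_patients"] = len(df)
        mean, median, rng, n_undef = _r2_stats(df["r2_fit"])
        row.update(
            r2_fit_mean=mean, r2_fit_median=median, r2_fit_range=rng,
            n_r2_fit_undefined=n_undef,
        )
        if "r2_ext" in df:
            mean, median, rng, _ = _r2_stats(df["r2_ext"])
            row.update(r2_ext_mean=mean, r2_ext_median=median, r2_ext_range=rng)
        if "mape" in df:
            row["mape_mean"] = float(df["mape"].dropna().mean()) if df["mape"].notna().any() else None
        return row

    rows = []
    if group_by:
        for key, df in results.groupby(group_by, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            rows.append(summarize(key, df))
    rows.append(summarize(tuple(["all"] * len(group_by)), results))
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    scales: ScaleConstants | None = None,
) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    t_start = time.monotonic()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    scales = scales or ScaleConstants(time_scale=config.time_scale)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.monotonic() - t_start:8.1f}s] {msg}")

    log(f"kuznefit {__version__} config={config.digest()} seed={config.seed}")

    # --- data ----------------------------------------------------------
    if config.data is None:
        spec = SyntheticSpec(
            n_patients=config.n_synthetic,
            ld_noise_sd=config.ld_noise_sd,
            seed=config.seed,
        )
        cohort, truths = generate_cohort(spec, scales)
        truth_table(truths).to_csv(out / "ground_truth.csv", index=False)
        write_cohort(cohort, out / "cohort.csv")
        log(f"generated synthetic cohort of {len(cohort)} patients")
    else:
        raw = read_cohort(config.data)
        cleaned = Cohort(
            records=[clean(r) for r in raw], provenance=raw.provenance
        )
        cohort = filter_cohort(cleaned, min_net=config.min_net)
        cohort = Cohort(
            records=[normalize(r, scales) for r in cohort],
            provenance=cohort.provenance,
        )
        log(
            f"read {len(raw)} patients from {config.data}; "
            f"{len(cohort)} retained after cleaning and the "
            f">= {config.min_net} net-measurement filter"
        )
        for r in cohort:
            for line in r.cleaning_log:
                log(f"clean: {line}")

    # --- fit -----------------------------------------------------------
    fit_cfg = FitConfig(
        n_starts=config.n_starts,
        max_evals=config.max_evals,
        max_time=config.max_time,
        seed=config.seed,
    )
    fits: dict[str, FitResult] = {}
    for rec in cohort:
        try:
            fit = fit_patient(rec, fit_cfg, scales)
        except Exception as exc:  # per-patient failures never abort the run
            log(f"fit: {rec.patient_id} FAILED ({exc})")
            continue
        fits[rec.patient_id] = fit
        status = "ok" if fit.success else "diverged"
        log(f"fit: {rec.patient_id} objective={fit.objective:.3e} "
            f"evals={fit.n_evals} status={status}")
    ok_ids = [pid for pid, f in fits.items() if f.success]
    fit_table = fits_to_table(list(fits.values()))
    fit_table.to_csv(out / "fits.csv", index=False)
    save_fits_json(list(fits.values()), out / "fits.json")

    # --- identifiability ----------------------------------------------
    if config.identify and ok_ids:
        ident_cfg = IdentConfig(
            epsilon=config.epsilon, max_evals=config.ident_max_evals, seed=config.seed
        )
        boxes = []
        for pid in ok_ids:
            try:
                box = parameter_box(cohort.get(pid), fits[pid], ident_cfg, fit_cfg, scales)
            except Exception as exc:
                log(f"identify: {pid} FAILED ({exc})")
                continue
            boxes.append(box)
            log(f"identify: {pid} widths={np.array2string(box.widths(), precision=2)}")
        if boxes:
            boxes_to_table(boxes).to_csv(out / "boxes.csv", index=False)
            range_frequency(boxes, fit_cfg=fit_cfg).to_csv(
                out / "range_frequency.csv", index=False
            )

    # --- prediction ----------------------------------------------------
    ext_results: list[ExtrapolationResult] = []
    envelopes: list[Envelope] = []
    if config.predict and ok_ids:
        pred_cfg = PredictConfig(
            zeta=config.zeta, theta=config.theta,
            max_evals=config.envelope_max_evals, seed=config.seed,
        )
        for pid in ok_ids:
            rec = cohort.get(pid)
            try:
                ext = fit_truncated(rec, pred_cfg, fit_cfg, scales)
                ext = extrapolate(ext, rec, scales)
                ext_results.append(ext)
                env = extreme_envelope(rec, ext, pred_cfg, fit_cfg, scales)
                envelopes.append(env)
                log(f"predict: {pid} mape={ext.mape:.3f} "
                    f"spread={env.terminal_spread():.3e}")
            except Exception as exc:
                log(f"predict: {pid} FAILED ({exc})")
        if ext_results:
            prediction_table(ext_results, envelopes).to_csv(
                out / "predictions.csv", index=False
            )
            traj_rows = []
            for ext, env in zip(ext_results, envelopes):
                rec = cohort.get(ext.patient_id)
                for branch, y in (
                    ("optimal", ext.predicted_full),
                    ("upper", env.upper.predicted_full),
                    ("lower", env.lower.predicted_full),
                ):
                    for t, v in zip(rec.tau, y):
                        traj_rows.append(
                            {"patient_id": ext.patient_id, "branch": branch,
                             "tau": t, "y": v}
                        )
            pd.DataFrame(traj_rows).to_csv(out / "trajectories.csv", index=False)

    # --- aggregate -----------------------------------------------------
    if not fit_table.empty:
        summary_in = fit_table.rename(columns={"r2": "r2_fit"})
        summary_in["study"] = [cohort.get(p).study_id for p in summary_in["patient_id"]]
        summary_in["arm"] = [cohort.get(p).arm_id for p in summary_in["patient_id"]]
        if ext_results:
            ext_df = prediction_table(ext_results).rename(columns={"r2": "r2_ext"})
            summary_in = summary_in.merge(
                ext_df[["patient_id", "r2_ext", "mape"]], on="patient_id", how="left"
            )
        aggregate(summary_in, group_by=("study", "arm")).to_csv(
            out / "summary.csv", index=False
        )

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    log(f"done in {time.monotonic() - t_start:.1f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
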