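"""Readers, writers, and run manifests binding the pipeline stages.

The on-disk dialects are plain text: a tidy samples CSV (one row per
trajectory sample, with the trial's start/target geometry repeated as
sidecar columns), tidy per-trial and per-session metrics CSVs, a YAML run
configuration, and posterior fits as an ArviZ NetCDF file next to a flat
summary CSV.  Readers accept either raw samples or precomputed per-trial
metrics (the deposited experimental data ship as the latter) and say which
they found.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fovadapt.metrics import Stage, TrialRecord

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["fish_id", "stage", "session", "trial", "t_s", "x_m", "y_m"]
SIDECAR_COLUMNS = ["x0", "y0", "xT", "yT"]
METRIC_COLUMNS = [
    "fish_id",
    "stage",
    "session",
    "trial",
    "success",
    "angular_error_deg",
    "len_m",
    "SE_m",
    "ET_m",
    "EAL_m",
    "d_m",
]


class SchemaError(ValueError):
    """Input file does not match any accepted dialect; lists every problem."""


def detect_dialect(df: pd.DataFrame) -> str:
    """'samples' for raw trajectories, 'metrics' for precomputed trials."""
    if {"t_s", "x_m", "y_m"}.issubset(df.columns):
        return "samples"
    if {"angular_error_deg", "d_m"}.issubset(df.columns) or {
        "angular_error_deg",
        "len_m",
    }.issubset(df.columns):
        return "metrics"
    raise SchemaError(
        "unrecognised input: expected samples columns (t_s, x_m, y_m) or "
        "metrics columns (angular_error_deg, len_m/d_m); got "
        f"{sorted(df.columns)}"
    )


def validate_columns(df: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def read_samples_csv(path) -> list[TrialRecord]:
    """Load raw trajectory samples into per-trial records."""
    df = pd.read_csv(path)
    validate_columns(df, SAMPLE_COLUMNS + SIDECAR_COLUMNS)
    records = []
    for (fish, stage, ses, trial), g in df.groupby(
        ["fish_id", "stage", "session", "trial"], sort=True
    ):
        g = g.sort_values("t_s")
        records.append(
            TrialRecord(
                fish_id=str(fish),
                stage=Stage(stage),
                session_index=int(ses),
                trial_index=int(trial),
                samples=g[["t_s", "x_m", "y_m"]].to_numpy(float),
                start_point=(float(g["x0"].iloc[0]), float(g["y0"].iloc[0])),
                target_point=(float(g["xT"].iloc[0]), float(g["yT"].iloc[0])),
                end_reason=g["end_reason"].iloc[0] if "end_reason" in g else None,
            )
        )
    records.sort(key=lambda r: (r.fish_id, r.stage.order, r.session_index, r.trial_index))
    return records


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_columns(df, ["fish_id", "stage", "session", "trial"])
    return df


def measure_observations(trial_df: pd.DataFrame, session_df: pd.DataFrame, measure) -> pd.DataFrame:
    """Extract the tidy (fish_id, session, value) frame a fit consumes."""
    from fovadapt.curves import MeasureFamily

    measure = MeasureFamily(measure)
    if measure is MeasureFamily.SUCCESS_POISSON:
        out = session_df.rename(columns={"success_count": "value"})[
            ["fish_id", "stage", "session", "value"]
        ].copy()
    else:
        col = "angular_error_deg" if measure is MeasureFamily.ANGULAR_STUDENT_T else "d_m"
        out = trial_df.rename(columns={col: "value"})[
            ["fish_id", "stage", "session", "trial", "value"]
        ].copy()
        out = out[np.isfinite(out["value"])]
    return out


def write_metrics(trial_df: pd.DataFrame, session_df: pd.DataFrame, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p1 = outdir / "trial_metrics.csv"
    p2 = outdir / "session_metrics.csv"
    trial_df.to_csv(p1, index=False)
    session_df.to_csv(p2, index=False)
    return p1, p2


def write_cohort(cohort, outdir) -> dict[str, Path]:
    """Write a synthetic cohort: samples CSV, truth table, config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.csv",
        "truth": outdir / "truth.csv",
        "config": outdir / "config.yaml",
    }
    cohort.samples.to_csv(paths["samples"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["stages"] = [
        dict(stage=s["stage"].value, n_sessions=s["n_sessions"], rotation_deg=s["rotation_deg"])
        for s in cfg["stages"]
    ]
    cfg["seed_used"] = cohort.seed
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths


def save_fit(fit, outdir, name: str = "fit") -> dict[str, Path]:
    """Persist a posterior fit: grouped draws (NetCDF) + flat summary CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nc = outdir / f"{name}.nc"
    fit.idata.to_netcdf(str(nc))
    summary = fit.summary()
    sp = outdir / f"{name}_summary.csv"
    summary.to_csv(sp)
    meta = outdir / f"{name}_meta.json"
    with open(meta, "w") as fh:
        json.dump(
            dict(
                family=fit.family.value,
                stage=fit.stage,
                fish_ids=fit.fish_ids,
                diagnostics=fit.diagnostics,
                flags=fit.flags,
                config=dataclasses.asdict(fit.config),
            ),
            fh,
            indent=2,
        )
    return {"draws": nc, "summary": sp, "meta": meta}


def load_fit(outdir, name: str = "fit"):
    import arviz as az

    from fovadapt.curves import MeasureFamily
    from fovadapt.inference import PosteriorFit, SamplerConfig

    outdir = Path(outdir)
    idata = az.from_netcdf(str(outdir / f"{name}.nc"))
    with open(outdir / f"{name}_meta.json") as fh:
        meta = json.load(fh)
    return PosteriorFit(
        idata=idata,
        family=MeasureFamily(meta["family"]),
        fish_ids=meta["fish_ids"],
        stage=meta["stage"],
        config=SamplerConfig(**meta["config"]),
        diagnostics=meta["diagnostics"],
        flags=meta["flags"],
    )


def write_manifest(outdir, *, command: str, seed: int | None, inputs: dict, extra: dict | None = None) -> Path:
    """Record inputs, seed, and package version so runs can be reproduced."""
    from fovadapt import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(
            dict(
                command=command,
                seed=seed,
                inputs={k: str(v) for k, v in inputs.items()},
                package="fovadapt",
                version=__version__,
                **(extra or {}),
            ),
            fh,
            indent=2,
        )
    return path


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
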