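"""End-to-end orchestration: cohort -> systemic hemodynamics -> per-vessel
CFD -> coherence statistics, into the study's result-table analogues.

The pipeline runs in synthetic mode (a seed and a :class:`CohortConfig`) or in
ingest mode (three relational CSVs: patients, vessels, velocities keyed by
patient_id/vessel_id). Each vessel is modelled as a straight constant-width
channel of its measured diameter and length, with the vessel's mean RBC
velocity as the uniform inlet velocity; the solved pressure difference is the
inlet-to-outlet area-weighted mean pressure drop.

Cohort CFD uses a reduced structured mesh (48 x 12 cells per vessel by
default): the discretization error of the straight-channel pressure drop at
that resolution is a few tenths of a percent, far below the between-vessel
geometric variability the statistics operate on, and it keeps a 60-vessel
cohort under a minute. The solver-validation studies use the full default
resolution (250 x 20).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, cohort_frames, generate_cohort, _config_to_jsonable
from .geometry import VesselSegment, mesh_vessel
from .hemodynamics import PatientRecord, derive
from .solver import (
    BoundaryConditions,
    ConvergenceError,
    FluidProperties,
    NumericsConfig,
    SolverError,
    solve_flow,
)
from .stats import (
    StatsError,
    bootstrap_correlation,
    compare_velocity_distributions,
    estimate_plateau,
    fit_lognormal,
    rank_correlation,
)

UM = 1e-6


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str, record_id: str | None = None):
        self.stage = stage
        self.record_id = record_id
        where = f" (record {record_id})" if record_id else ""
        super().__init__(f"pipeline stage {stage!r} failed{where}: {msg}")


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    # reduced per-vessel mesh for cohort batches (see module docstring)
    n_axial: int = 48
    n_transverse: int = 12
    bootstrap_resamples: int = 30
    write_fields: bool = False          # export per-vessel VTK fields
    # ingest mode: paths to the three relational CSVs (overrides synthesis)
    patients_csv: str | None = None
    vessels_csv: str | None = None
    velocities_csv: str | None = None

    @property
    def seed(self) -> int:
        return self.cohort.seed


@dataclass
class CohortResult:
    """Joined per-patient / per-vessel results plus the statistical tables."""

    patients: pd.DataFrame
    vessels: pd.DataFrame
    velocities: pd.DataFrame
    correlations: pd.DataFrame
    summary: pd.DataFrame
    plateau: object
    kruskal: tuple[float, float]
    bootstrap: dict
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "cohort": _config_to_jsonable(config.cohort),
            "mesh": [config.n_axial, config.n_transverse],
            "fluid": [config.fluid.density, config.fluid.kinematic_viscosity],
            "bootstrap": config.bootstrap_resamples,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_frames(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    if config.patients_csv:
        if not (config.vessels_csv and config.velocities_csv):
            raise PipelineError("ingest", "all three CSV paths are required")
        return {
            "patients": pd.read_csv(config.patients_csv),
            "vessels": pd.read_csv(config.vessels_csv),
            "velocities": pd.read_csv(config.velocities_csv),
        }
    patients = generate_cohort(config.cohort)
    return cohort_frames(patients, config.cohort)


def _hemodynamics_stage(patients: pd.DataFrame) -> pd.DataFrame:
    rows = []
    rec_fields = {
        "patient_id", "age", "height", "weight", "heart_rate", "sap", "dap",
        "map", "cvp", "co", "sao2", "scvo2", "pao2", "hb", "sv", "svv",
        "svr", "paco2", "lactate",
    }
    for _, row in patients.iterrows():
        kwargs = {k: row[k] for k in rec_fields if k in patients.columns}
        kwargs["patient_id"] = str(kwargs["patient_id"])
        try:
            d = derive(PatientRecord(**kwargs))
        except Exception as exc:  # noqa: BLE001 - halt with context per contract
            raise PipelineError("hemodynamics", str(exc), kwargs["patient_id"])
        rows.append(d.__dict__)
    derived = pd.DataFrame(rows)
    # ingested tables may already carry derived columns; recompute wins
    stale = [c for c in derived.columns if c != "patient_id" and c in patients.columns]
    return patients.drop(columns=stale).merge(derived, on="patient_id")


def _cfd_stage(
    vessels: pd.DataFrame, config: PipelineConfig, outdir: Path | None
) -> pd.DataFrame:
    out = vessels.copy()
    dps, res, its, ok, reason = [], [], [], [], []
    for _, row in out.iterrows():
        seg = VesselSegment.straight(
            row["diameter"], row["length"], row["mean_velocity"],
            vessel_id=str(row["vessel_id"]),
        )
        try:
            mesh = mesh_vessel(seg, config.n_axial, config.n_transverse)
            sol = solve_flow(
                mesh,
                fluid=config.fluid,
                bc=BoundaryConditions(inlet_velocity=row["mean_velocity"] * UM),
                numerics=config.numerics,
            )
            dps.append(sol.pressure_difference())
            res.append(sol.reynolds)
            its.append(sol.iterations)
            ok.append(True)
            reason.append("")
            if config.write_fields and outdir is not None:
                sol.to_vtk(outdir / f"field_{row['vessel_id']}.vtk")
        except (SolverError, ValueError) as exc:
            dps.append(np.nan)
            res.append(np.nan)
            its.append(0)
            ok.append(False)
            reason.append(f"{type(exc).__name__}: {exc}")
    out["dp"] = dps
    out["reynolds"] = res
    out["iterations"] = its
    out["converged"] = ok
    out["excluded_reason"] = reason
    return out


_SUMMARY_VARS = [
    "heart_rate", "sap", "dap", "map", "co", "sv", "svv", "svr", "cvp",
    "pmca", "pg_vr", "r_vr", "do2", "vo2", "o2er", "pao2", "paco2", "hb",
    "lactate", "sao2", "scvo2", "mean_velocity", "max_velocity",
]

_CORR_PAIRS = [
    ("pmca", "co"), ("pmca", "map"), ("pmca", "svr"), ("pmca", "pg_vr"),
    ("pmca", "r_vr"), ("pmca", "mean_velocity"), ("pmca", "max_velocity"),
    ("pmca", "mean_length"), ("pmca", "dp_patient"),
    ("mean_velocity", "mean_diameter"), ("mean_velocity", "mean_length"),
    ("mean_velocity", "o2er"),
    ("pmca", "de_backer"), ("pmca", "de_backer_small"),
    ("pmca", "consensus_ppv"), ("pmca", "consensus_ppv_small"),
]


def _stats_stage(
    patients: pd.DataFrame,
    vessels: pd.DataFrame,
    velocities: pd.DataFrame,
    config: PipelineConfig,
):
    cfg_hash = _config_hash(config)
    seed = config.seed

    # per-patient velocity distributions
    groups = [g["velocity"].to_numpy() for _, g in velocities.groupby("patient_id")]
    kw = compare_velocity_distributions(groups)
    fits = {
        pid: fit_lognormal(g["velocity"].to_numpy())
        for pid, g in velocities.groupby("patient_id")
    }
    patients = patients.drop(
        columns=[
            c
            for c in ("fit_mu_log", "fit_sigma_log", "fit_ks_p", "dp_patient",
                      "mean_diameter", "mean_length")
            if c in patients.columns
        ]
    )
    patients["fit_mu_log"] = patients["patient_id"].map(
        lambda i: fits[i].mu_log if i in fits else np.nan
    )
    patients["fit_sigma_log"] = patients["patient_id"].map(
        lambda i: fits[i].sigma_log if i in fits else np.nan
    )
    patients["fit_ks_p"] = patients["patient_id"].map(
        lambda i: fits[i].ks_p if i in fits else np.nan
    )

    # aggregate converged per-vessel CFD to the patient level
    conv = vessels[vessels["converged"]]
    agg = conv.groupby("patient_id").agg(
        dp_patient=("dp", "mean"),
        mean_diameter=("diameter", "mean"),
        mean_length=("length", "mean"),
    )
    patients = patients.merge(agg, on="patient_id", how="left")

    plateau = estimate_plateau(
        patients["pmca"].to_numpy(), patients["mean_velocity"].to_numpy(),
        band=config.cohort.coherence_params.plateau_band,
    )

    rows = []
    for xcol, ycol in _CORR_PAIRS:
        if xcol not in patients.columns or ycol not in patients.columns:
            continue
        sub = patients[[xcol, ycol]].dropna()
        for method in ("kendall", "spearman"):
            try:
                r = rank_correlation(sub[xcol], sub[ycol], method)
            except StatsError:
                continue
            rows.append(
                {
                    "x": xcol, "y": ycol, "unit": "patient", "method": method,
                    "coefficient": r.coefficient, "p_value": r.p_value,
                    "n": r.n, "seed": seed, "config_hash": cfg_hash,
                }
            )

    # the Pmca - dp coherence correlation, bootstrapped at both units
    bootstrap = {}
    vconv = vessels.merge(patients[["patient_id", "pmca"]], on="patient_id")
    vconv = vconv[vconv["converged"]]
    for unit, (x, y) in {
        "patient": (patients.dropna(subset=["dp_patient"])["pmca"],
                    patients.dropna(subset=["dp_patient"])["dp_patient"]),
        "vessel": (vconv["pmca"], vconv["dp"]),
    }.items():
        if len(x) < 5:
            continue
        bs = bootstrap_correlation(
            x, y, "kendall", n_resamples=config.bootstrap_resamples,
            seed=seed + 211,
        )
        bootstrap[unit] = bs
        lo, hi = bs.ci
        rows.append(
            {
                "x": "pmca", "y": "dp", "unit": unit, "method": "kendall-bootstrap",
                "coefficient": bs.point_estimate, "p_value": bs.p_value,
                "n": bs.plug_in.n, "ci_low": lo, "ci_high": hi,
                "seed": seed, "config_hash": cfg_hash,
            }
        )
    correlations = pd.DataFrame(rows)

    present = [v for v in _SUMMARY_VARS if v in patients.columns]
    summary = pd.DataFrame(
        {
            "variable": present,
            "mean": [patients[v].mean() for v in present],
            "sd": [patients[v].std() for v in present],
        }
    )
    return patients, correlations, plateau, kw, bootstrap, summary


def run_pipeline(config: PipelineConfig | None = None, outdir=None) -> CohortResult:
    """Run the full chain; deterministic given the cohort seed.

    Writes intermediate artifacts and result tables under ``outdir`` when
    given (cohort CSVs, result tables, a JSON run manifest; VTK fields when
    ``config.write_fields``).
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}

    t0 = time.perf_counter()
    frames = _load_frames(config)
    timing["cohort"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    patients = _hemodynamics_stage(frames["patients"])
    timing["hemodynamics"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    vessels = _cfd_stage(frames["vessels"], config, outdir)
    timing["cfd"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        patients, correlations, plateau, kw, bootstrap, summary = _stats_stage(
            patients, vessels, frames["velocities"], config
        )
    except StatsError as exc:
        raise PipelineError("stats", str(exc))
    timing["stats"] = time.perf_counter() - t0

    n_conv = int(vessels["converged"].sum())
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_patients": int(len(patients)),
        "n_vessels": int(len(vessels)),
        "n_converged": n_conv,
        "stage_seconds": {k: round(v, 3) for k, v in timing.items()},
        "kruskal_h": kw[0],
        "kruskal_p": kw[1],
    }
    result = CohortResult(
        patients=patients,
        vessels=vessels,
        velocities=frames["velocities"],
        correlations=correlations,
        summary=summary,
        plateau=plateau,
        kruskal=kw,
        bootstrap=bootstrap,
        manifest=manifest,
    )
    if outdir is not None:
        report_tables(result, outdir)
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def report_tables(result: CohortResult, outdir) -> dict[str, Path]:
    """Write the result-table analogues as CSVs.

    summary (mean +/- sd per systemic variable), correlations, the
    Pmca-vs-velocity pairs, and the Pmca-vs-dp pairs at both units of
    analysis (one row per converged vessel in the per-vessel file).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = result.summary.copy()
    summary["mean_sd"] = [
        f"{m:.1f} ± {s:.1f}" for m, s in zip(summary["mean"], summary["sd"])
    ]
    paths["summary"] = outdir / "table_summary.csv"
    summary.to_csv(paths["summary"], index=False)

    paths["correlations"] = outdir / "table_correlations.csv"
    result.correlations.to_csv(paths["correlations"], index=False)

    paths["pmca_velocity"] = outdir / "fig_pmca_velocity.csv"
    result.patients[
        ["patient_id", "mean_velocity", "max_velocity", "pmca", "regime"]
        if "regime" in result.patients.columns
        else ["patient_id", "mean_velocity", "max_velocity", "pmca"]
    ].to_csv(paths["pmca_velocity"], index=False)

    paths["pmca_dp_patient"] = outdir / "fig_pmca_dp_patient.csv"
    result.patients[["patient_id", "pmca", "dp_patient"]].to_csv(
        paths["pmca_dp_patient"], index=False
    )
    vconv = result.vessels[result.vessels["converged"]].merge(
        result.patients[["patient_id", "pmca"]], on="patient_id"
    )
    paths["pmca_dp_vessel"] = outdir / "fig_pmca_dp_vessel.csv"
    vconv[["patient_id", "vessel_id", "pmca", "dp", "reynolds"]].to_csv(
        paths["pmca_dp_vessel"], index=False
    )

    paths["patients"] = outdir / "cohort_patients_derived.csv"
    result.patients.to_csv(paths["patients"], index=False)
    paths["vessels"] = outdir / "cohort_vessels_cfd.csv"
    result.vessels.to_csv(paths["vessels"], index=False)
    return paths
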