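"""Synthetic cohort generator for the hemodynamic-coherence pipeline.

Emulates the statistical structure of a 20-patient anesthetized cohort in
steady-state physiology: cohort-level systemic means/SDs, per-patient
log-normal sublingual RBC velocity distributions with patient-specific means,
sublingual vessel diameter/length distributions, and the piecewise
Pmca-velocity coupling (a Pmca plateau of 14 mmHg for patient mean velocities
in the 6-24 um/s band; Pmca below 14 mmHg for faster patients).

Generative direction
--------------------
velocity regime first -> Pmca target -> cardiac output back-solved from the
Pmca model, so that both the coherence coupling and the Pmca algebra hold
exactly on every generated record. Ground-truth labels (patient log-velocity
parameters, pre-noise Pmca, regime) are retained for recovery tests.

Pooled RBC velocities are exactly log-normal: with pooled moment-matched
parameters (mu0, sigma_tot) and a within-patient log-sd sigma_w, patient
medians are drawn log-normally with spread tau = sqrt(sigma_tot^2 - sigma_w^2)
and samples within a patient share sigma_w, so the mixture pools back to
LN(mu0, sigma_tot) with the configured linear mean and sd.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamics import (
    A_VENOUS,
    B_ARTERIAL,
    HemodynamicsError,
    PatientRecord,
    compute_c_coefficient,
)

_MAX_REJECTIONS = 1000


class CohortConfigError(ValueError):
    """Configuration cannot generate a valid cohort."""


@dataclass
class VelocityParams:
    """Cohort-pooled RBC velocity targets (um/s) and the per-patient shape."""

    mean: float = 15.0
    sd: float = 9.0
    #: Within-patient log-normal sigma; the between-patient spread is the
    #: remainder of the pooled log-variance.
    within_sigma_log: float = 0.25
    #: Multiply to convert pixel-unit velocities to um/s when ingesting
    #: external data; the generator itself works in um/s.
    pixel_to_um: float = 1.0
    #: Patients with true mean velocity below this floor are excluded (the
    #: slow regime has no reported Pmca behaviour); the between-patient
    #: location is shifted so the *accepted* cohort still pools to ``mean``.
    exclusion_floor: float = 6.0

    @property
    def sigma_log_total(self) -> float:
        return math.sqrt(math.log(1.0 + (self.sd / self.mean) ** 2))

    @property
    def mu_log(self) -> float:
        return math.log(self.mean) - 0.5 * self.sigma_log_total**2

    @property
    def between_sigma_log(self) -> float:
        var = self.sigma_log_total**2 - self.within_sigma_log**2
        if var < 0:
            raise CohortConfigError(
                "within-patient log-sd exceeds the pooled log-sd implied by "
                "the cohort mean/sd"
            )
        return math.sqrt(var)

    def mu_log_between(self) -> float:
        """Location of the between-patient log-mean distribution.

        Without the slow-regime exclusion this is the moment-matched
        ``mu_log``; with a positive ``exclusion_floor`` the left truncation
        of the patient-mean distribution would bias the pooled mean upward,
        so the location is shifted (closed-form conditional expectation of a
        truncated log-normal, solved numerically) to keep the accepted
        cohort's pooled mean at ``mean``.
        """
        tau = self.between_sigma_log
        if tau == 0 or self.sd == 0 or self.exclusion_floor <= 0:
            return self.mu_log
        from scipy.optimize import brentq
        from scipy.stats import norm

        c = math.log(self.exclusion_floor)

        def pooled_mean(nu):
            # E[exp(Y) | Y >= c] for Y ~ N(nu, tau): patient log-means
            accept = norm.sf((c - nu) / tau)
            return (
                math.exp(nu + 0.5 * tau**2)
                * norm.sf((c - nu - tau**2) / tau)
                / accept
            )

        nu0 = self.mu_log + 0.5 * self.within_sigma_log**2
        nu = brentq(lambda t: pooled_mean(t) - self.mean, nu0 - 2.0, nu0 + 0.5)
        return nu - 0.5 * self.within_sigma_log**2


@dataclass
class VesselParams:
    """Sublingual vessel geometry targets (um)."""

    diameter_mean: float = 17.2
    diameter_sd: float = 4.0
    length_mean: float = 137.3
    length_sd: float = 96.8
    #: Truncation floors keeping segments meshable (documented limitation:
    #: the truncated length mean exceeds length_mean because sd > mean/2).
    diameter_min: float = 5.0
    length_min: float = 30.0


@dataclass
class CoherenceParams:
    """Piecewise Pmca-velocity coupling."""

    plateau_pmca: float = 14.0          # mmHg
    plateau_band: tuple[float, float] = (6.0, 24.0)  # um/s, closed band
    plateau_jitter_sd: float = 0.25     # mmHg, so the plateau rounds to 14.0
    fast_velocity_pmca_range: tuple[float, float] = (11.0, 14.0)  # mmHg


@dataclass
class CohortConfig:
    n_patients: int = 20
    vessels_per_patient: int = 3     # "best three videos" per subject
    samples_per_vessel: int = 40     # per-vessel RBC velocity samples
    seed: int = 0
    #: Cohort-level (mean, sd) per systemic variable; SaO2 has sd 0.
    systemic_params: dict = field(
        default_factory=lambda: {
            "heart_rate": (67.5, 7.0),
            "map": (88.1, 7.0),
            "pulse_pressure": (48.7, 7.0),
            "cvp": (7.1, 0.7),
            "sv": (74.7, 9.6),
            "svv": (5.9, 1.8),
            "svr": (1306.3, 176.3),
            "sao2": (100.0, 0.0),
            "scvo2": (74.2, 2.3),
            "pao2": (92.5, 5.1),
            "paco2": (39.2, 1.3),
            "hb": (14.1, 0.94),
            "lactate": (0.8, 0.2),
        }
    )
    demographics: dict = field(
        default_factory=lambda: {
            "age": (40.0, 5.0, 18.0, 65.0),
            "height": (175.0, 10.0, 140.0, 210.0),
            "weight": (75.0, 12.0, 40.0, 140.0),
        }
    )
    vessel_params: VesselParams = field(default_factory=VesselParams)
    velocity_params: VelocityParams = field(default_factory=VelocityParams)
    coherence_params: CoherenceParams = field(default_factory=CoherenceParams)
    #: Sublingual density/flow scores, sampled as pass-through columns.
    score_params: dict = field(
        default_factory=lambda: {
            "de_backer": (3.7, 1.2),
            "de_backer_small": (2.0, 1.1),
            "consensus_ppv": (94.2, 5.7),
            "consensus_ppv_small": (88.2, 10.0),
        }
    )

    def validate(self) -> "CohortConfig":
        if self.n_patients < 2:
            raise CohortConfigError("n_patients must be >= 2")
        lo, hi = self.coherence_params.plateau_band
        if not lo < hi:
            raise CohortConfigError("plateau_band must be (low, high) with low < high")
        for name, (mean, sd) in self.systemic_params.items():
            if sd < 0:
                raise CohortConfigError(f"negative sd for {name}")
        self.velocity_params.between_sigma_log  # raises if inconsistent
        return self


@dataclass
class VesselSample:
    """One vessel's generated geometry and velocity data (um, um/s)."""

    vessel_id: str
    diameter: float
    length: float
    velocities: np.ndarray

    @property
    def mean_velocity(self) -> float:
        return float(np.mean(self.velocities))


@dataclass
class SyntheticPatient:
    record: PatientRecord
    vessels: list[VesselSample]
    # generative ground truth for parameter-recovery tests
    true_mu_log: float
    true_sigma_log: float
    true_mean_velocity: float       # um/s, pre-noise patient mean
    true_pmca: float                # mmHg, pre-rounding Pmca target
    regime: str                     # "plateau" | "fast"

    @property
    def velocities(self) -> np.ndarray:
        return np.concatenate([v.velocities for v in self.vessels])

    @property
    def sampled_mean_velocity(self) -> float:
        return float(np.mean(self.velocities))


def sample_patient_velocity_distribution(
    rng: np.random.Generator, velocity_params: VelocityParams
) -> tuple[float, float]:
    """Draw one patient's log-normal velocity parameters ``(mu_log, sigma_log)``.

    Patient medians are spread with the between-patient log-sd so the cohort
    pools back to the configured linear mean and sd (moment matching):
    ``sigma_tot^2 = ln(1 + sd^2/mean^2)``, ``mu0 = ln(mean) - sigma_tot^2/2``.
    """
    vp = velocity_params
    if vp.sd == 0:
        return math.log(vp.mean), 0.0
    mu_i = rng.normal(vp.mu_log_between(), vp.between_sigma_log)
    return mu_i, vp.within_sigma_log


def assign_coherent_pmca(
    rng: np.random.Generator,
    patient_mean_velocity: float,
    coherence_params: CoherenceParams,
) -> float:
    """Pmca target (mmHg) for a patient mean RBC velocity (um/s).

    Velocities in the closed plateau band get the plateau value plus Gaussian
    jitter; faster patients draw uniformly from the sub-plateau range. The
    band is closed at its upper edge (24 um/s belongs to the plateau); the
    slow regime below the band is not generated by default and is flagged.
    """
    cp = coherence_params
    lo, hi = cp.plateau_band
    v = patient_mean_velocity
    if not v > 0:
        raise CohortConfigError("patient mean velocity must be positive")
    if v < lo:
        raise CohortConfigError(
            f"velocity {v:.2f} um/s below the plateau band; the slow regime "
            "has no reported Pmca behaviour and is not generated"
        )
    if v <= hi:
        # jitter truncated at 3 sigma so the plateau is a bounded band
        return cp.plateau_pmca + _trunc_normal(
            rng, 0.0, cp.plateau_jitter_sd,
            -3.0 * cp.plateau_jitter_sd, 3.0 * cp.plateau_jitter_sd,
        )
    a, b = cp.fast_velocity_pmca_range
    return float(rng.uniform(a, b))


def invert_pmca_for_co(
    pmca_target: float, cvp: float, map_: float, c: float
) -> float:
    """Back-solve cardiac output (L/min) so the Pmca model hits ``pmca_target``.

    Raises :class:`HemodynamicsError` when the implied CO is non-positive
    (the caller treats this as a resample signal).
    """
    if not c > 0:
        raise HemodynamicsError("c coefficient must be strictly positive")
    co = (pmca_target - A_VENOUS * cvp - B_ARTERIAL * map_) / c
    if not co > 0:
        raise HemodynamicsError(
            "pmca target implies non-positive cardiac output; resample"
        )
    return co


def _trunc_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float = -np.inf,
    high: float = np.inf,
) -> float:
    """Truncated normal by rejection; exact for the modest truncations used."""
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(_MAX_REJECTIONS):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    raise CohortConfigError(
        f"truncated-normal rejection limit reached for mean={mean}, sd={sd}, "
        f"bounds=({low}, {high})"
    )


def _sample_patient(
    rng: np.random.Generator, config: CohortConfig, index: int
) -> SyntheticPatient:
    cfg = config
    sp = cfg.systemic_params
    vp = cfg.velocity_params
    cp = cfg.coherence_params

    for _ in range(_MAX_REJECTIONS):
        # demographics -> c coefficient
        age_m, age_s, age_lo, age_hi = cfg.demographics["age"]
        h_m, h_s, h_lo, h_hi = cfg.demographics["height"]
        w_m, w_s, w_lo, w_hi = cfg.demographics["weight"]
        age = _trunc_normal(rng, age_m, age_s, age_lo, age_hi)
        height = _trunc_normal(rng, h_m, h_s, h_lo, h_hi)
        weight = _trunc_normal(rng, w_m, w_s, w_lo, w_hi)
        c = compute_c_coefficient(age, height, weight)

        # velocity regime (reject patient means below the plateau band)
        mu_i, sigma_w = sample_patient_velocity_distribution(rng, vp)
        true_mean = math.exp(mu_i + 0.5 * sigma_w**2)
        if true_mean < max(cp.plateau_band[0], vp.exclusion_floor):
            continue
        pmca_target = assign_coherent_pmca(rng, true_mean, cp)
        regime = "plateau" if true_mean <= cp.plateau_band[1] else "fast"

        # systemic pressures, then CO back-solved from the Pmca model
        cvp = _trunc_normal(rng, *sp["cvp"], low=1.0)
        map_ = _trunc_normal(rng, *sp["map"], low=cvp + 20.0)
        try:
            co = invert_pmca_for_co(pmca_target, cvp, map_, c)
        except HemodynamicsError:
            continue

        pulse = _trunc_normal(rng, *sp["pulse_pressure"], low=10.0)
        dap = map_ - pulse / 3.0
        sap = dap + pulse
        sao2 = _trunc_normal(rng, *sp["sao2"], high=100.0)
        scvo2 = _trunc_normal(rng, *sp["scvo2"], low=20.0, high=sao2 - 1.0)
        record = PatientRecord(
            patient_id=f"P{index + 1:03d}",
            age=age,
            height=height,
            weight=weight,
            heart_rate=_trunc_normal(rng, *sp["heart_rate"], low=30.0),
            sap=sap,
            dap=dap,
            map=map_,
            cvp=cvp,
            co=co,
            sao2=sao2,
            scvo2=scvo2,
            pao2=_trunc_normal(rng, *sp["pao2"], low=40.0),
            hb=_trunc_normal(rng, *sp["hb"], low=5.0),
            sv=_trunc_normal(rng, *sp["sv"], low=20.0),
            svv=_trunc_normal(rng, *sp["svv"], low=0.0),
            svr=_trunc_normal(rng, *sp["svr"], low=300.0),
            paco2=_trunc_normal(rng, *sp["paco2"], low=20.0),
            lactate=_trunc_normal(rng, *sp["lactate"], low=0.1),
        ).validate()

        vessels = []
        ves = cfg.vessel_params
        for k in range(cfg.vessels_per_patient):
            diameter = _trunc_normal(
                rng, ves.diameter_mean, ves.diameter_sd, low=ves.diameter_min
            )
            length = _trunc_normal(
                rng,
                ves.length_mean,
                ves.length_sd,
                low=max(ves.length_min, 2.0 * diameter),
            )
            velocities = rng.lognormal(mu_i, sigma_w, size=cfg.samples_per_vessel)
            vessels.append(
                VesselSample(
                    vessel_id=f"{record.patient_id}-V{k + 1}",
                    diameter=diameter,
                    length=length,
                    velocities=velocities,
                )
            )

        return SyntheticPatient(
            record=record,
            vessels=vessels,
            true_mu_log=mu_i,
            true_sigma_log=sigma_w,
            true_mean_velocity=true_mean,
            true_pmca=pmca_target,
            regime=regime,
        )

    raise CohortConfigError(
        f"exceeded {_MAX_REJECTIONS} consecutive rejections generating a "
        "patient; the configuration is inconsistent with the coherence model"
    )


def generate_cohort(config: CohortConfig | None = None) -> list[SyntheticPatient]:
    """Generate ``config.n_patients`` synthetic patients, deterministically
    for a given seed (one spawned RNG stream per patient)."""
    cfg = (config or CohortConfig()).validate()
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients)
    return [
        _sample_patient(np.random.default_rng(s), cfg, i)
        for i, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# Relational-table export: patients / vessels / velocities keyed by id,
# plus a JSON sidecar with the config, seed and generative ground truth.
# ---------------------------------------------------------------------------

def cohort_frames(
    patients: list[SyntheticPatient], config: CohortConfig | None = None
) -> dict[str, pd.DataFrame]:
    score_rows = None
    if config is not None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        score_rows = {
            p.record.patient_id: {
                name: _trunc_normal(rng, m, s, low=0.0, high=100.0 if "ppv" in name else np.inf)
                for name, (m, s) in config.score_params.items()
            }
            for p in patients
        }

    prow = []
    for p in patients:
        row = dict(p.record.__dict__)
        row.update(
            mean_velocity=p.true_mean_velocity,
            sampled_mean_velocity=p.sampled_mean_velocity,
            max_velocity=float(np.max(p.velocities)),
            regime=p.regime,
            true_pmca=p.true_pmca,
            true_mu_log=p.true_mu_log,
            true_sigma_log=p.true_sigma_log,
        )
        if score_rows is not None:
            row.update(score_rows[p.record.patient_id])
        prow.append(row)

    vrow = [
        {
            "patient_id": p.record.patient_id,
            "vessel_id": v.vessel_id,
            "diameter": v.diameter,
            "length": v.length,
            "mean_velocity": v.mean_velocity,
        }
        for p in patients
        for v in p.vessels
    ]
    srow = [
        {"patient_id": p.record.patient_id, "vessel_id": v.vessel_id, "velocity": u}
        for p in patients
        for v in p.vessels
        for u in v.velocities
    ]
    return {
        "patients": pd.DataFrame(prow),
        "vessels": pd.DataFrame(vrow),
        "velocities": pd.DataFrame(srow),
    }


def write_cohort(
    patients: list[SyntheticPatient], config: CohortConfig, outdir
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = cohort_frames(patients, config)
    paths = {}
    for name, df in frames.items():
        paths[name] = outdir / f"cohort_{name}.csv"
        df.to_csv(paths[name], index=False)
    sidecar = {
        "seed": config.seed,
        "config": _config_to_jsonable(config),
        "ground_truth": [
            {
                "patient_id": p.record.patient_id,
                "true_mu_log": p.true_mu_log,
                "true_sigma_log": p.true_sigma_log,
                "true_mean_velocity": p.true_mean_velocity,
                "true_pmca": p.true_pmca,
                "regime": p.regime,
            }
            for p in patients
        ],
    }
    paths["sidecar"] = outdir / "cohort_config.json"
    paths["sidecar"].write_text(json.dumps(sidecar, indent=1))
    return paths


def _config_to_jsonable(config: CohortConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        return obj

    return conv(config)
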