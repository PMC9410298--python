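"""Systemic hemodynamics: the mean circulatory filling pressure analogue (Pmca)
and derived venous-return / oxygen-transport variables.

The Pmca model is Guytonian: the systemic circulation is collapsed into a venous
and an arterial compartment with a 24:1 compliance ratio, giving compartment
weights ``a = 0.96`` (venous) and ``b = 0.04`` (arterial, ``a + b = 1``), plus a
flow-dependent term whose coefficient ``c`` stands for the arteriovenous
resistance and is computed from age, height and weight (the denominator is the
DuBois body-surface-area formula, which fixes the units to years / cm / kg):

    Pmca = a*CVP + b*MAP + c*CO
    c = 0.038 * (94.17 + 0.193*age)
        / (4.5 * 0.99**(age - 15) * 0.007184 * height**0.725 * weight**0.425)

Derived quantities: the pressure gradient for venous return PG_VR = Pmca - CVP,
the resistance to venous return R_VR = PG_VR / CO, the oxygen extraction ratio
O2ER = (SaO2 - ScvO2)/SaO2, and Fick-convention oxygen delivery/consumption
DO2/VO2 (Hufner constant 1.34 mL O2 per g Hb by default, dissolved term
0.003 mL O2 / dL / mmHg; ScvO2 substitutes for mixed venous saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable

import pandas as pd

#: Venous compartment weight (24:1 veno-arterial compliance ratio).
A_VENOUS = 0.96
#: Arterial compartment weight; A_VENOUS + B_ARTERIAL == 1 by construction.
B_ARTERIAL = 0.04
#: Oxygen-binding capacity of hemoglobin, mL O2 per g Hb.
HUFNER_CONSTANT = 1.34
#: Solubility of O2 in plasma, mL O2 per dL per mmHg.
O2_SOLUBILITY = 0.003

assert A_VENOUS + B_ARTERIAL == 1.0


class HemodynamicsError(ValueError):
    """Domain error for non-physiologic or ill-posed inputs."""


class RecordValidationError(HemodynamicsError):
    """Raised by :meth:`PatientRecord.validate`; lists *all* violations."""

    def __init__(self, patient_id: str, violations: list[str]):
        self.patient_id = patient_id
        self.violations = list(violations)
        msg = f"record {patient_id!r} failed validation: " + "; ".join(violations)
        super().__init__(msg)


def _require_positive(**named_values: float) -> None:
    bad = [name for name, v in named_values.items() if not (v > 0)]
    if bad:
        raise HemodynamicsError(
            "expected strictly positive value(s) for: " + ", ".join(bad)
        )


def compute_c_coefficient(age: float, height: float, weight: float) -> float:
    """Arteriovenous-resistance coefficient ``c`` in mmHg·min/L.

    Parameters
    ----------
    age : years
    height : cm
    weight : kg

    The denominator contains the DuBois body-surface-area term
    ``0.007184 * height**0.725 * weight**0.425`` (m^2), which is what pins the
    units of height and weight.
    """
    _require_positive(age=age, height=height, weight=weight)
    numerator = 0.038 * (94.17 + 0.193 * age)
    denominator = (
        4.5
        * 0.99 ** (age - 15.0)
        * 0.007184
        * height**0.725
        * weight**0.425
    )
    return numerator / denominator


def compute_pmca(cvp: float, map_: float, co: float, c: float) -> float:
    """Mean circulatory filling pressure analogue, mmHg.

    ``Pmca = 0.96*CVP + 0.04*MAP + c*CO``; affine in every argument.
    """
    if co < 0:
        raise HemodynamicsError("cardiac output must be non-negative")
    if c < 0:
        raise HemodynamicsError("c coefficient must be non-negative")
    return A_VENOUS * cvp + B_ARTERIAL * map_ + c * co


def compute_pg_vr(pmca: float, cvp: float) -> float:
    """Pressure gradient for venous return, mmHg: ``Pmca - CVP``."""
    return pmca - cvp


def compute_r_vr(pmca: float, cvp: float, co: float) -> float:
    """Resistance to venous return, mmHg·min/L: ``(Pmca - CVP)/CO``."""
    if not co > 0:
        raise HemodynamicsError("cardiac output must be strictly positive")
    return (pmca - cvp) / co


def compute_o2er(sao2: float, scvo2: float) -> float:
    """Oxygen extraction ratio as a dimensionless fraction in [0, 1].

    ``O2ER = (SaO2 - ScvO2)/SaO2`` with saturations in percent (0-100).
    Rendered as a percentage only at the reporting layer.
    """
    if not (0 < sao2 <= 100):
        raise HemodynamicsError("sao2 must lie in (0, 100]")
    if not (0 <= scvo2 <= sao2):
        raise HemodynamicsError(
            "scvo2 must lie in [0, sao2]; venous saturation above arterial "
            "is non-physiologic"
        )
    return (sao2 - scvo2) / sao2


def compute_do2_vo2(
    co: float,
    hb: float,
    sao2: float,
    scvo2: float,
    pao2: float,
    hufner: float = HUFNER_CONSTANT,
) -> tuple[float, float]:
    """Oxygen delivery and consumption (Fick convention), both in mL/min.

    DO2 = CO * CaO2 * 10 with CaO2 = hufner*Hb*SaO2/100 + 0.003*PaO2 (mL/dL);
    VO2 = CO * hufner*Hb*(SaO2 - ScvO2)/100 * 10 (dissolved O2 neglected in the
    a-v difference, so VO2/DO2 equals O2ER up to the dissolved term).
    The factor 10 converts L/min * mL/dL to mL/min.
    """
    _require_positive(co=co, hb=hb)
    if pao2 < 0:
        raise HemodynamicsError("pao2 must be non-negative")
    compute_o2er(sao2, scvo2)  # reuse saturation domain checks
    cao2 = hufner * hb * sao2 / 100.0 + O2_SOLUBILITY * pao2
    do2 = co * cao2 * 10.0
    vo2 = co * hufner * hb * (sao2 - scvo2) / 100.0 * 10.0
    return do2, vo2


@dataclass
class PatientRecord:
    """One subject's demographics, systemic hemodynamics and oximetry."""

    patient_id: str
    age: float            # years
    height: float         # cm
    weight: float         # kg
    heart_rate: float     # beats/min
    sap: float            # systolic arterial pressure, mmHg
    dap: float            # diastolic arterial pressure, mmHg
    map: float            # mean arterial pressure, mmHg
    cvp: float            # central venous pressure, mmHg
    co: float             # cardiac output, L/min
    sao2: float           # arterial O2 saturation, % (0-100)
    scvo2: float          # central venous O2 saturation, % (0-100)
    pao2: float           # arterial O2 partial pressure, mmHg
    hb: float             # hemoglobin, g/dL
    sv: float = float("nan")       # stroke volume, mL/beat (pass-through)
    svv: float = float("nan")      # stroke volume variation, %
    svr: float = float("nan")      # systemic vascular resistance, dyn·s·cm^-5
    paco2: float = float("nan")    # mmHg
    lactate: float = float("nan")  # mmol/L

    def validate(self) -> "PatientRecord":
        """Check the record invariants, collecting *all* violations."""
        v: list[str] = []
        if not self.age > 0:
            v.append("age must be > 0")
        if not self.height > 0:
            v.append("height must be > 0")
        if not self.weight > 0:
            v.append("weight must be > 0")
        if not self.co > 0:
            v.append("cardiac output must be > 0")
        if not self.map > self.cvp:
            v.append("mean arterial pressure must exceed CVP")
        if not (0 <= self.scvo2 <= self.sao2 <= 100):
            v.append("saturations must satisfy 0 <= ScvO2 <= SaO2 <= 100")
        if v:
            raise RecordValidationError(self.patient_id, v)
        return self


@dataclass
class DerivedHemodynamics:
    """Pmca and its derived variables for one patient record.

    Pressures in mmHg, resistances in mmHg·min/L, O2ER as a fraction,
    DO2/VO2 in mL/min. ``pg_vr == pmca - cvp`` and ``r_vr == pg_vr/co``
    hold exactly by construction.
    """

    patient_id: str
    c_coefficient: float
    pmca: float
    pg_vr: float
    r_vr: float
    o2er: float
    do2: float
    vo2: float
    #: True when pg_vr <= 0; such records are flagged, never silently dropped.
    nonpositive_gradient: bool = field(default=False)


def derive(record: PatientRecord, hufner: float = HUFNER_CONSTANT) -> DerivedHemodynamics:
    """Compute the full derived-variable set for a validated patient record."""
    record.validate()
    c = compute_c_coefficient(record.age, record.height, record.weight)
    pmca = compute_pmca(record.cvp, record.map, record.co, c)
    pg_vr = compute_pg_vr(pmca, record.cvp)
    r_vr = compute_r_vr(pmca, record.cvp, record.co)
    o2er = compute_o2er(record.sao2, record.scvo2)
    do2, vo2 = compute_do2_vo2(
        record.co, record.hb, record.sao2, record.scvo2, record.pao2, hufner=hufner
    )
    return DerivedHemodynamics(
        patient_id=record.patient_id,
        c_coefficient=c,
        pmca=pmca,
        pg_vr=pg_vr,
        r_vr=r_vr,
        o2er=o2er,
        do2=do2,
        vo2=vo2,
        nonpositive_gradient=pg_vr <= 0,
    )


# ---------------------------------------------------------------------------
# CSV interface. One row per patient; header names match PatientRecord fields.
# ---------------------------------------------------------------------------

def read_patient_records(path) -> list[PatientRecord]:
    """Read patient records from CSV (one row per patient) and validate them."""
    df = pd.read_csv(path)
    names = {f.name for f in fields(PatientRecord)}
    records = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in names}
        kwargs["patient_id"] = str(kwargs["patient_id"])
        records.append(PatientRecord(**kwargs).validate())
    return records


def derived_frame(derived: Iterable[DerivedHemodynamics]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in derived])


def write_derived(derived: Iterable[DerivedHemodynamics], path) -> pd.DataFrame:
    """Write derived variables to CSV, pressures rounded to 1 decimal at write
    time only (full precision is retained on the in-memory objects)."""
    df = derived_frame(derived).copy()
    for col in ("pmca", "pg_vr"):
        df[col] = df[col].round(1)
    for col in ("c_coefficient", "r_vr", "o2er"):
        df[col] = df[col].round(4)
    for col in ("do2", "vo2"):
        df[col] = df[col].round(1)
    df.to_csv(path, index=False)
    return df
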