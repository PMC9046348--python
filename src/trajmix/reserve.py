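"""Deficit-accumulation physiologic reserve index over 39 health variables.

Each variable (clinical labs, comorbidity flags, HIV-disease indicators) is
dichotomized as normal (1) or deficit (0) by a fixed criterion; the index is
the number of normal variables divided by the number of available
variables, ranging 0 (all deficits) to 1 (no deficits).  Higher scores mean
more physiologic reserve; the complement is a conventional frailty index.

The criteria live in a versioned, machine-readable rules file
(``reserve_criteria.yaml``); inequalities are strict except where the rule
states >=, so boundary values score normal in all but the triglyceride
criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

NORMAL, DEFICIT = "normal", "deficit"


class ReserveError(ValueError):
    pass


def _load_criteria():
    text = (
        resources.files("trajmix").joinpath("reserve_criteria.yaml").read_text()
    )
    spec = yaml.safe_load(text)
    return spec["version"], spec["items"]


CRITERIA_VERSION, CRITERIA = _load_criteria()
ITEM_NAMES = tuple(item["name"] for item in CRITERIA)
_BY_NAME = {item["name"]: item for item in CRITERIA}
SEX_SPECIFIC = tuple(
    item["name"] for item in CRITERIA if item["kind"].endswith("_sex")
)

assert len(ITEM_NAMES) == 39


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def dichotomize(item_name: str, measurement, sex: str = None) -> str:
    """Score one health variable as ``'normal'`` or ``'deficit'``.

    ``measurement`` is in the item's native units (booleans for comorbidity
    flags; for hypertension a mapping with keys ``diagnosis``, ``systolic``,
    ``diastolic``).  Sex-specific cutoffs require ``sex``.
    """
    if item_name not in _BY_NAME:
        raise ReserveError(f"unknown reserve item: {item_name!r}")
    rule = _BY_NAME[item_name]
    kind = rule["kind"]
    if kind.endswith("_sex"):
        if sex not in ("male", "female"):
            raise ReserveError(
                f"item {item_name!r} has sex-specific cutoffs; sex is required"
            )
    if kind == "flag":
        return DEFICIT if bool(measurement) else NORMAL
    if kind == "hypertension":
        m = dict(measurement)
        if bool(m.get("diagnosis", False)):
            return DEFICIT
        sbp, dbp = m.get("systolic"), m.get("diastolic")
        if (sbp is not None and sbp > rule["systolic"]) or (
            dbp is not None and dbp > rule["diastolic"]
        ):
            return DEFICIT
        return NORMAL
    x = float(measurement)
    if kind == "low":
        return DEFICIT if x < rule["value"] else NORMAL
    if kind == "high":
        return DEFICIT if x > rule["value"] else NORMAL
    if kind == "ge":
        return DEFICIT if x >= rule["value"] else NORMAL
    if kind == "outside":
        return DEFICIT if (x < rule["lo"] or x > rule["hi"]) else NORMAL
    if kind == "low_sex":
        return DEFICIT if x < rule[sex] else NORMAL
    if kind == "outside_sex":
        band = rule[sex]
        return DEFICIT if (x < band["lo"] or x > band["hi"]) else NORMAL
    raise ReserveError(f"unhandled rule kind: {kind!r}")  # pragma: no cover


@dataclass
class ReserveProfile:
    """One participant's 39 health measurements (missing items allowed).

    ``values`` maps item name -> measurement; absent or NaN entries are
    treated as unavailable and excluded from both numerator and denominator.
    """

    values: dict = field(default_factory=dict)
    sex: str = None

    def available(self):
        return [
            n for n in ITEM_NAMES
            if n in self.values and not _is_missing(self.values[n])
        ]


@dataclass
class ReserveIndex:
    value: float
    n_available: int
    n_normal: int


def reserve_index(profile: ReserveProfile) -> ReserveIndex:
    """Proportion of available health variables scored normal."""
    avail = profile.available()
    if not avail:
        raise ReserveError("no reserve items available")
    if profile.sex is None and any(n in SEX_SPECIFIC for n in avail):
        raise ReserveError("sex is required for sex-specific items")
    n_normal = sum(
        dichotomize(n, profile.values[n], profile.sex) == NORMAL for n in avail
    )
    return ReserveIndex(n_normal / len(avail), len(avail), n_normal)


def reserve_index_from_deficits(deficits) -> ReserveIndex:
    """Index from pre-dichotomized items (1 = deficit, NaN = unavailable)."""
    arr = np.asarray(deficits, dtype=float)
    avail = ~np.isnan(arr)
    n_avail = int(avail.sum())
    if n_avail == 0:
        raise ReserveError("no reserve items available")
    n_normal = int((arr[avail] == 0).sum())
    return ReserveIndex(n_normal / n_avail, n_avail, n_normal)


#: an all-normal exemplar profile: every item satisfies its normal condition.
ALL_NORMAL_EXAMPLE = {
    "bmi": 22.0, "wbc": 6000.0, "mchc": 30.0, "bun": 15.0,
    "creatinine": 0.9, "calcium": 9.8, "chloride": 101.0,
    "total_protein": 7.0, "albumin": 4.2, "fibrinogen": 3.0, "egfr": 90.0,
    "hemoglobin": 14.0, "ast": 25.0, "alt": 25.0, "alp": 80.0,
    "potassium": 4.2, "bilirubin": 0.8, "triglycerides": 120.0,
    "cholesterol": 180.0, "hdl": 55.0, "glucose": 90.0,
    "weight_loss": False, "platelets": 250.0, "hcv": False,
    "diabetes": False, "copd": False, "malignancy": False,
    "myocardial_infarction": False, "renal_disease": False,
    "hypertension": {"diagnosis": False, "systolic": 118.0, "diastolic": 76.0},
    "hyperlipidemia": False, "cerebrovascular_accident": False,
    "sensory_neuropathy": False, "neuropathic_pain": False, "smoking": False,
    "current_cd4": 600.0, "nadir_cd4": 300.0, "hiv_rna": 20.0,
    "disease_duration": 5.0,
}

#: an all-deficit exemplar profile: every item violates its criterion.
ALL_DEFICIT_EXAMPLE = {
    "bmi": 31.0, "wbc": 3000.0, "mchc": 35.0, "bun": 30.0,
    "creatinine": 1.8, "calcium": 8.0, "chloride": 110.0,
    "total_protein": 8.5, "albumin": 3.0, "fibrinogen": 4.0, "egfr": 45.0,
    "hemoglobin": 9.0, "ast": 60.0, "alt": 60.0, "alp": 150.0,
    "potassium": 5.8, "bilirubin": 2.0, "triglycerides": 210.0,
    "cholesterol": 240.0, "hdl": 30.0, "glucose": 250.0,
    "weight_loss": True, "platelets": 100.0, "hcv": True,
    "diabetes": True, "copd": True, "malignancy": True,
    "myocardial_infarction": True, "renal_disease": True,
    "hypertension": {"diagnosis": True, "systolic": 150.0, "diastolic": 95.0},
    "hyperlipidemia": True, "cerebrovascular_accident": True,
    "sensory_neuropathy": True, "neuropathic_pain": True, "smoking": True,
    "current_cd4": 350.0, "nadir_cd4": 150.0, "hiv_rna": 10000.0,
    "disease_duration": 15.0,
}
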