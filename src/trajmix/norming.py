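"""Demographic-regression norming and practice-effect correction.

Raw neuropsychological test scores are converted to T-scores (mean 50, SD
10) via a linear main-effects regression of raw score on age, education,
sex, and race/ethnicity fitted to a normative sample.  The "peak-age"
transform substitutes age 25 -- roughly the peak of fluid cognition -- for
chronological age in the prediction, so a peak-age T of 40 means
performance one residual SD below the expectation for a 25-year-old with
the same education, sex and race/ethnicity.  Practice effects from repeat
testing are removed as additive, visit-indexed raw-score adjustments before
norming.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trajmix.synth import DOMAINS, RACE_LEVELS

PEAK_AGE = 25.0


class NormingError(ValueError):
    pass


@dataclass
class NormModel:
    """Fitted normative regression for one test/domain.

    Prediction is affine in (age, education, male indicator, race dummies
    relative to ``race_levels[0]``).  ``residual_sd`` is in raw-score units.
    """

    intercept: float
    age: float
    education: float
    male: float
    race_effects: dict          # level -> offset; reference level maps to 0.0
    residual_sd: float
    fitted_on: str = ""

    def predict(self, demographics: dict) -> float:
        for fld in ("age", "education", "sex", "race"):
            if fld not in demographics or demographics[fld] is None:
                raise NormingError(f"missing demographic field: {fld!r}")
        race = demographics["race"]
        if race not in self.race_effects:
            raise NormingError(
                f"race/ethnicity level {race!r} absent from the normative "
                f"sample; refusing to extrapolate (known: "
                f"{sorted(self.race_effects)})"
            )
        return (
            self.intercept
            + self.age * float(demographics["age"])
            + self.education * float(demographics["education"])
            + self.male * (1.0 if demographics["sex"] == "male" else 0.0)
            + self.race_effects[race]
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "age": self.age,
            "education": self.education,
            "male": self.male,
            "race_effects": dict(self.race_effects),
            "residual_sd": self.residual_sd,
            "fitted_on": self.fitted_on,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormModel":
        return cls(**d)


@dataclass
class PracticeModel:
    """Additive expected raw-score gain at each repeat exposure.

    ``expected_gain_by_visit[0]`` is 0 by construction; visits beyond the
    schedule reuse the final gain (documented behaviour, not an error).
    """

    expected_gain_by_visit: tuple

    def __post_init__(self):
        if len(self.expected_gain_by_visit) == 0:
            raise NormingError("practice model needs at least visit 0")
        if self.expected_gain_by_visit[0] != 0.0:
            raise NormingError("practice gain at visit 0 must be 0")

    def gain(self, visit_index: int) -> float:
        if visit_index < 0:
            raise NormingError("visit_index must be >= 0")
        sched = self.expected_gain_by_visit
        return float(sched[min(visit_index, len(sched) - 1)])

    def to_dict(self) -> dict:
        return {"expected_gain_by_visit": list(self.expected_gain_by_visit)}

    @classmethod
    def from_dict(cls, d: dict) -> "PracticeModel":
        return cls(tuple(d["expected_gain_by_visit"]))


def save_models(models: dict, path) -> None:
    """Serialize a dict of NormModel/PracticeModel to JSON."""
    payload = {}
    for name, m in models.items():
        payload[name] = {"type": type(m).__name__, **m.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for name, d in payload.items():
        kind = d.pop("type")
        out[name] = (NormModel if kind == "NormModel" else PracticeModel).from_dict(d)
    return out


# ---------------------------------------------------------------------------


def fit_norms(norm_sample: pd.DataFrame, raw_col: str,
              provenance: str = "synthetic normative sample") -> NormModel:
    """Least-squares demographic regression of ``raw_col`` on the sample.

    Requires every demographic stratum (both sexes, >= 2 race levels) so the
    model never silently extrapolates downstream; raises on rank-deficient
    designs, naming the offending columns.
    """
    need = {"age", "education", "sex", "race", raw_col}
    missing = need - set(norm_sample.columns)
    if missing:
        raise NormingError(f"norm sample lacks columns: {sorted(missing)}")
    races = [r for r in RACE_LEVELS if r in set(norm_sample["race"])]
    extra = set(norm_sample["race"]) - set(RACE_LEVELS)
    races += sorted(extra)
    absent = [r for r in RACE_LEVELS if r not in races]
    if absent:
        raise NormingError(
            f"race/ethnicity level(s) {absent} absent from the normative "
            "sample; all strata used downstream must be represented"
        )
    male = (norm_sample["sex"] == "male").to_numpy(dtype=float)
    cols = ["const", "age", "education", "male"] + [
        f"race[{r}]" for r in races[1:]
    ]
    X = np.column_stack(
        [
            np.ones(len(norm_sample)),
            norm_sample["age"].to_numpy(dtype=float),
            norm_sample["education"].to_numpy(dtype=float),
            male,
        ]
        + [
            (norm_sample["race"] == r).to_numpy(dtype=float)
            for r in races[1:]
        ]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by checking rank drop on removal
        bad = []
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(cols[j])
        raise NormingError(f"rank-deficient normative design; collinear "
                           f"columns: {bad}")
    y = norm_sample[raw_col].to_numpy(dtype=float)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    race_effects = {races[0]: 0.0}
    for j, r in enumerate(races[1:]):
        race_effects[r] = float(beta[4 + j])
    return NormModel(
        intercept=float(beta[0]),
        age=float(beta[1]),
        education=float(beta[2]),
        male=float(beta[3]),
        race_effects=race_effects,
        residual_sd=residual_sd,
        fitted_on=provenance,
    )


def fit_all_norms(norm_sample: pd.DataFrame) -> dict:
    """Fit one NormModel per battery domain (columns ``raw_<domain>``)."""
    return {
        name: fit_norms(norm_sample, f"raw_{name}") for name in DOMAINS
    }


def fit_practice(retest_sample: pd.DataFrame) -> PracticeModel:
    """Estimate additive practice gains from a no-true-change retest sample.

    The gain at visit v is the mean within-person raw-score change from
    visit 0, pooled over tests.
    """
    need = {"id", "visit", "domain", "raw"}
    if not need <= set(retest_sample.columns):
        raise NormingError(f"retest sample needs columns {sorted(need)}")
    wide = retest_sample.pivot_table(
        index=["id", "domain"], columns="visit", values="raw"
    )
    base = wide[0]
    gains = [0.0]
    for v in sorted(wide.columns)[1:]:
        gains.append(float((wide[v] - base).mean()))
    return PracticeModel(tuple(gains))


def correct_practice(raw, visit_index: int, pm: PracticeModel):
    """Remove the expected practice gain from a raw score (visit 0: no-op)."""
    return np.asarray(raw, dtype=float) - pm.gain(visit_index)


def peak_age_tscore(raw, demographics: dict, nm: NormModel) -> float:
    """T-score against age-25 normative expectations.

    ``T = 50 + 10 * (raw - prediction at age 25) / residual_sd``.
    """
    demo = dict(demographics)
    if "age" not in demo or demo["age"] is None:
        raise NormingError("missing demographic field: 'age'")
    demo["age"] = PEAK_AGE
    pred = nm.predict(demo)
    return 50.0 + 10.0 * (np.asarray(raw, dtype=float) - pred) / nm.residual_sd


def chronological_tscore(raw, demographics: dict, nm: NormModel) -> float:
    """T-score against same-chronological-age normative expectations."""
    pred = nm.predict(dict(demographics))
    return 50.0 + 10.0 * (np.asarray(raw, dtype=float) - pred) / nm.residual_sd


def global_tscore(domain_ts) -> float:
    """Arithmetic mean of the available domain T-scores.

    Returns NaN (with a warning) when every domain is missing.
    """
    arr = np.asarray(domain_ts, dtype=float)
    if np.all(np.isnan(arr)):
        warnings.warn("global T-score undefined: all domain scores missing")
        return float("nan")
    return float(np.nanmean(arr))
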