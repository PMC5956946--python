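"""Cohort-construction rules and declarative comparator risk scores.

Three concerns live here:

* the ordered baseline exclusion filters that turn a raw cohort into the
  analytic sample (race, prevalent T2DM/CHD/stroke, missing MetS
  components, non-fasting labs, no diabetes follow-up), with a tally of how
  many participants each filter removed;
* the outcome rules — per-visit T2DM status under the ARIC and JHS
  diagnostic protocols, the dichotomous 10-year T2DM outcome, and
  min-of-dates CHD follow-up;
* evaluation of published-style risk equations from a declarative
  :class:`RiskScoreSpec` (10-year survival, logistic, or ordinal point
  scores), plus in-sample Z-standardisation of the resulting score column.

Coefficient values for real published equations are deliberately not
hard-coded: specs are editable YAML files and the bundled ones carry
synthetic placeholder coefficients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .synthetic_cohort import TEN_YEARS_DAYS, CohortTable

__all__ = [
    "RiskScoreSpec",
    "ScoreTerm",
    "PointsRule",
    "ScoreColumn",
    "apply_exclusions",
    "EXCLUSION_ORDER",
    "t2dm_status",
    "t2dm_10yr_outcome",
    "chd_followup",
    "compute_score",
    "standardize",
]

#: ordered exclusion filters; a participant counts toward the first filter
#: that removes them
EXCLUSION_ORDER = (
    "other_race",
    "baseline_t2dm",
    "baseline_chd",
    "baseline_stroke",
    "missing_components",
    "non_fasting",
    "no_t2dm_followup",
)

_MET_COMPONENTS = ("waist", "triglycerides", "hdl", "sbp", "glucose")


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(cohort: CohortTable) -> tuple[CohortTable, dict[str, int]]:
    """Apply the ordered baseline filters; return analytic cohort + tally.

    The tally attributes each removed participant to the first filter that
    caught them, so the tally entries sum to ``input n - analytic n``.  An
    empty analytic sample is allowed (a warning is emitted).
    """
    df = cohort.participants
    masks = {
        "other_race": ~df["race"].isin(["white", "black"]),
        "baseline_t2dm": df["flag_baseline_t2dm"].astype(bool),
        "baseline_chd": df["flag_baseline_chd"].astype(bool),
        "baseline_stroke": df["flag_baseline_stroke"].astype(bool),
        "missing_components": df[list(_MET_COMPONENTS)].isna().any(axis=1),
        "non_fasting": ~df["baseline_fasting"].astype(bool),
        "no_t2dm_followup": df["flag_no_followup"].astype(bool),
    }
    removed = np.zeros(len(df), dtype=bool)
    tally: dict[str, int] = {}
    for name in EXCLUSION_ORDER:
        hit = masks[name].to_numpy() & ~removed
        tally[name] = int(hit.sum())
        removed |= hit
    keep = df.loc[~removed]
    if keep.empty:
        import warnings

        warnings.warn("all participants excluded; analytic sample is empty")
    visits = cohort.visits[cohort.visits["participant_id"].isin(keep["participant_id"])]
    return CohortTable(participants=keep, visits=visits), tally


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def t2dm_status(visits: pd.DataFrame, cohort_protocol: str) -> pd.Series:
    """Per-visit T2DM status under a study protocol.

    ARIC: self-reported physician diagnosis, fasting glucose >= 126 mg/dL,
    non-fasting glucose >= 200 mg/dL, or diabetes medication use.
    JHS: fasting glucose >= 126 mg/dL, HbA1c >= 6.5%, or diabetes medication
    within two weeks of the visit (supplied as the medication boolean).
    JHS ignores self-report; ARIC ignores HbA1c.
    """
    fasting = visits["fasting"].astype(bool)
    glucose = visits["glucose"].astype(float)
    meds = visits["on_diabetes_medication"].astype(bool)
    if cohort_protocol == "ARIC":
        status = (
            visits["self_report_diagnosis"].astype(bool)
            | (fasting & (glucose >= 126.0))
            | (~fasting & (glucose >= 200.0))
            | meds
        )
    elif cohort_protocol == "JHS":
        status = (fasting & (glucose >= 126.0)) | (visits["hba1c"].astype(float) >= 6.5) | meds
    else:
        raise ValueError(f"unknown protocol {cohort_protocol!r}")
    return status.rename("t2dm_status")


def t2dm_10yr_outcome(cohort: CohortTable, horizon_days: int = TEN_YEARS_DAYS) -> pd.Series:
    """Dichotomous 10-year T2DM outcome per participant.

    True iff any follow-up visit (visit index >= 2) within ``horizon_days``
    of baseline is status-positive under the participant's protocol.
    """
    visits = cohort.visits
    proto = cohort.participants.set_index("participant_id")["protocol"]
    fup = visits[(visits["visit_index"] >= 2) & (visits["days_since_baseline"] <= horizon_days)].copy()
    fup["protocol"] = fup["participant_id"].map(proto)
    positive = pd.Series(False, index=fup.index)
    for p in ("ARIC", "JHS"):
        sel = fup["protocol"] == p
        if sel.any():
            positive.loc[sel] = t2dm_status(fup.loc[sel], p).to_numpy()
    hit = fup.loc[positive.to_numpy(), "participant_id"].unique()
    out = pd.Series(False, index=cohort.participants["participant_id"].to_numpy(), name="t2dm_10y")
    out.loc[out.index.isin(hit)] = True
    return out


def chd_followup(
    event_day,
    death_day,
    last_contact_day,
    admin_end_day: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Min-of-dates CHD follow-up resolution.

    Follow-up time is the minimum of first CHD event, death from other
    causes, last contact, and the administrative end of follow-up; the event
    indicator is true only when the minimum is the CHD event (an event tied
    with a censoring date counts as an event).  NaN marks an absent date.
    """
    ev = np.atleast_1d(np.asarray(event_day, dtype=float))
    de = np.atleast_1d(np.asarray(death_day, dtype=float))
    lc = np.atleast_1d(np.asarray(last_contact_day, dtype=float))
    for arr, label in ((ev, "event"), (de, "death"), (lc, "last contact")):
        if np.any(arr[np.isfinite(arr)] < 0):
            raise ValueError(f"negative {label} day")
    if admin_end_day < 0:
        raise ValueError("negative administrative end day")
    stacked = np.column_stack(
        [
            np.where(np.isnan(ev), np.inf, ev),
            np.where(np.isnan(de), np.inf, de),
            np.where(np.isnan(lc), np.inf, lc),
            np.full(ev.shape, float(admin_end_day)),
        ]
    )
    time = stacked.min(axis=1)
    if not np.all(np.isfinite(time)):
        raise ValueError("at least one of event/death/last-contact/admin must be defined")
    event = stacked[:, 0] <= time
    if np.isscalar(event_day) or np.ndim(event_day) == 0:
        return float(time[0]), bool(event[0])
    return time, event


# ---------------------------------------------------------------------------
# declarative risk scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreTerm:
    """One linear-predictor term; ``stratum`` restricts it to a sex value
    ('man'/'woman') or a full subgroup label ('white-man', ...)."""

    covariate: str
    coefficient: float
    transform: str = "identity"
    stratum: str | None = None


@dataclass
class PointsRule:
    """Ordinal-points rule: either threshold bins over a numeric covariate
    (``len(points) == len(cuts) + 1``) or fixed points when the covariate
    equals a value."""

    covariate: str
    cuts: list[float] | None = None
    points: list[int] | None = None
    equals: object | None = None
    points_if_equal: int | None = None

    def evaluate(self, values: pd.Series) -> np.ndarray:
        if self.equals is not None:
            return np.where(values.to_numpy() == self.equals, int(self.points_if_equal), 0)
        if self.cuts is None or self.points is None or len(self.points) != len(self.cuts) + 1:
            raise ValueError(f"malformed points rule for {self.covariate!r}")
        idx = np.searchsorted(np.asarray(self.cuts, dtype=float), values.to_numpy(float), side="right")
        return np.asarray(self.points, dtype=int)[idx]


@dataclass
class RiskScoreSpec:
    """Declarative description of a published-style risk equation."""

    name: str
    outcome_family: str  # survival10y | logistic | ordinal_points
    terms: list[ScoreTerm] = field(default_factory=list)
    s0: float | dict[str, float] | None = None
    mean_lp: float | dict[str, float] = 0.0
    intercept: float = 0.0
    points_rules: list[PointsRule] = field(default_factory=list)
    standardize_flag: bool = True

    def __post_init__(self) -> None:
        if self.outcome_family not in ("survival10y", "logistic", "ordinal_points"):
            raise ValueError(f"unknown outcome_family {self.outcome_family!r}")
        if self.outcome_family == "survival10y" and self.s0 is None:
            raise ValueError("survival10y spec requires baseline 10-year survival s0")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskScoreSpec":
        d = dict(d)
        d["terms"] = [ScoreTerm(**t) for t in d.get("terms", [])]
        d["points_rules"] = [PointsRule(**r) for r in d.get("points_rules", [])]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RiskScoreSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ScoreColumn:
    """Raw and (optionally) in-sample Z-standardised score values."""

    name: str
    raw: pd.Series
    standardized: pd.Series | None = None
    mean: float | None = None
    sd: float | None = None
    standardize_flag: bool = True

    @property
    def modelling(self) -> pd.Series:
        """Column used for HR/OR display: standardised when flagged."""
        return self.standardized if (self.standardize_flag and self.standardized is not None) else self.raw


def _stratum_mask(df: pd.DataFrame, stratum: str | None) -> np.ndarray:
    if stratum is None:
        return np.ones(len(df), dtype=bool)
    if stratum in ("man", "woman"):
        return (df["sex"] == stratum).to_numpy()
    return (df["subgroup"] == stratum).to_numpy()


def _resolve_stratified(value, df: pd.DataFrame, what: str) -> np.ndarray:
    if isinstance(value, Mapping):
        out = np.full(len(df), np.nan)
        for key, v in value.items():
            out[_stratum_mask(df, key)] = float(v)
        if np.any(np.isnan(out)):
            raise ValueError(f"stratified {what} does not cover all rows")
        return out
    return np.full(len(df), float(value))


def compute_score(cohort: CohortTable | pd.DataFrame, spec: RiskScoreSpec) -> ScoreColumn:
    """Evaluate a risk-score spec for every participant.

    survival10y returns the predicted 10-year risk ``1 - s0**exp(lp - mean_lp)``,
    logistic a probability, ordinal_points an integer score.
    """
    df = cohort.participants if isinstance(cohort, CohortTable) else cohort
    idx = df["participant_id"].to_numpy() if "participant_id" in df.columns else df.index.to_numpy()

    if spec.outcome_family == "ordinal_points":
        total = np.zeros(len(df), dtype=int)
        for rule in spec.points_rules:
            if rule.covariate not in df.columns:
                raise KeyError(f"missing covariate {rule.covariate!r}")
            total = total + rule.evaluate(df[rule.covariate])
        values = total.astype(float)
    else:
        lp = np.zeros(len(df), dtype=float)
        for term in spec.terms:
            if term.covariate not in df.columns:
                raise KeyError(f"missing covariate {term.covariate!r}")
            x = df[term.covariate].to_numpy(dtype=float)
            if term.transform == "log":
                if np.any(x <= 0):
                    raise ValueError(f"log transform of non-positive {term.covariate!r}")
                x = np.log(x)
            elif term.transform != "identity":
                raise ValueError(f"unknown transform {term.transform!r}")
            lp += term.coefficient * x * _stratum_mask(df, term.stratum)
        if spec.outcome_family == "survival10y":
            s0 = _resolve_stratified(spec.s0, df, "s0")
            mean_lp = _resolve_stratified(spec.mean_lp, df, "mean_lp")
            values = 1.0 - s0 ** np.exp(lp - mean_lp)
        else:
            values = expit(spec.intercept + lp)
    raw = pd.Series(values, index=idx, name=spec.name)
    return ScoreColumn(name=spec.name, raw=raw, standardize_flag=spec.standardize_flag)


def standardize(column: ScoreColumn | pd.Series, flag: bool = True) -> ScoreColumn:
    """In-sample Z-standardisation ``(x - mean) / sd``; identity when
    ``flag`` is false (e.g. the ordinal diabetes points score)."""
    if isinstance(column, ScoreColumn):
        raw = column.raw
        name = column.name
    else:
        raw = column
        name = column.name or "score"
    if not flag:
        return ScoreColumn(name=name, raw=raw, standardized=None, standardize_flag=False)
    if len(raw) < 2:
        raise ValueError("need at least two observations to standardise")
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if sd == 0:
        raise ValueError("cannot standardise a constant score column")
    z = (raw - mean) / sd
    return ScoreColumn(name=name, raw=raw, standardized=z.rename(f"{name}_z"), mean=mean, sd=sd, standardize_flag=True)
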