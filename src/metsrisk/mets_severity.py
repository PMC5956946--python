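"""Sex- and race-specific MetS severity Z-score via one-factor CFA.

The severity score is a continuous alternative to the dichotomous
metabolic-syndrome diagnosis: the five traditional components (waist
circumference, triglycerides, HDL cholesterol, systolic BP, fasting glucose)
are transformed (log for right-skewed triglycerides by default),
standardised against a reference sample, and combined with the loadings of a
one-factor confirmatory factor model.  Signs are normalised so that a higher
score always means worse metabolic status (positive loading on glucose,
negative on HDL), and the final score is rescaled so the reference sample
has mean 0 and SD 1 — the "per SD of MetS severity" unit used when the score
enters risk models.

Loadings can either be fitted here (:func:`fit_cfa_loadings`) or supplied as
a published-coefficient YAML file; provenance is recorded on the object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import FactorAnalysis

from .synthetic_cohort import COMPONENTS, CohortTable

__all__ = [
    "MetSLoadings",
    "fit_cfa_loadings",
    "mets_z",
    "score_cohort",
    "homa_ir",
    "save_loadings",
    "load_loadings",
    "DEFAULT_TRANSFORMS",
]

DEFAULT_TRANSFORMS = {
    "waist": "identity",
    "triglycerides": "log",
    "hdl": "identity",
    "sbp": "identity",
    "glucose": "identity",
}

#: a common factor must load substantially on at least two components; the
#: fit is flagged degenerate when the second-largest |loading| falls below
#: this (a "factor" loading on a single variable is indistinguishable from
#: that variable's unique variance)
DEGENERACY_THRESHOLD = 0.15


class CFAConvergenceError(RuntimeError):
    """Raised when the one-factor fit fails or a component is degenerate."""


@dataclass
class MetSLoadings:
    """Scoring equation for one sex-by-race subgroup.

    ``score = scale * (sum_k loading_k * z_k - offset)`` where
    ``z_k = (transform_k(x_k) - mean_k) / sd_k`` uses reference-sample
    standardisation constants.  By construction the reference sample scores
    to mean 0, SD 1, and a participant at the reference means scores exactly
    0 (``offset`` is the reference mean of the weighted sum, which is 0 when
    the constants come from the same sample).
    """

    subgroup: str
    transforms: dict[str, str]
    means: dict[str, float]
    sds: dict[str, float]
    loadings: dict[str, float]
    offset: float = 0.0
    scale: float = 1.0
    degenerate: bool = False
    provenance: str = "cfa-fit"

    def __post_init__(self) -> None:
        missing = [c for c in COMPONENTS if c not in self.loadings]
        if missing or len(self.loadings) != len(COMPONENTS):
            raise ValueError(f"loadings must cover exactly the 5 components; missing {missing}")
        for c in COMPONENTS:
            if self.sds[c] <= 0:
                raise ValueError(f"standardisation SD for {c} must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetSLoadings":
        return cls(**dict(d))


def _transform(values: np.ndarray, tag: str, component: str) -> np.ndarray:
    if tag == "identity":
        return np.asarray(values, dtype=float)
    if tag == "log":
        v = np.asarray(values, dtype=float)
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValueError(f"log transform of non-positive {component}")
        return np.log(v)
    raise ValueError(f"unknown transform {tag!r}")


def fit_cfa_loadings(
    reference: CohortTable | pd.DataFrame,
    subgroup: str,
    transforms: Mapping[str, str] | None = None,
) -> MetSLoadings:
    """Fit the one-factor scoring equation on a reference sample.

    Parameters
    ----------
    reference
        Cohort (or participant table) containing the subgroup rows; rows
        with any missing component are dropped.
    subgroup
        Label matched against the ``subgroup`` column.
    transforms
        Per-component transform tags; defaults to log triglycerides.

    Raises
    ------
    CFAConvergenceError
        If fewer than 200 complete subgroup rows are available, a component
        has zero variance, or the factor fit fails.
    """
    df = reference.participants if isinstance(reference, CohortTable) else reference
    tr = dict(DEFAULT_TRANSFORMS if transforms is None else transforms)
    sub = df.loc[df["subgroup"] == subgroup, list(COMPONENTS)].dropna()
    if len(sub) < 200:
        raise CFAConvergenceError(
            f"need >= 200 complete participants for subgroup {subgroup!r}, got {len(sub)}"
        )
    X = np.column_stack([_transform(sub[c].to_numpy(), tr[c], c) for c in COMPONENTS])
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = COMPONENTS[int(np.argmin(sds))]
        raise CFAConvergenceError(f"zero-variance component {bad!r}")
    Z = (X - means) / sds

    fa = FactorAnalysis(n_components=1, svd_method="lapack", max_iter=2000, tol=1e-4)
    try:
        fa.fit(Z)
    except Exception as exc:  # pragma: no cover - sklearn failure surface
        raise CFAConvergenceError(f"one-factor fit failed: {exc}") from exc
    if fa.n_iter_ >= 2000:
        raise CFAConvergenceError("one-factor fit did not converge")
    lam = fa.components_[0].astype(float)

    # sign normalisation: higher score = worse metabolic status
    g = COMPONENTS.index("glucose")
    if lam[g] < 0:
        lam = -lam
    degenerate = bool(np.sort(np.abs(lam))[-2] < DEGENERACY_THRESHOLD)

    raw = Z @ lam
    offset = float(raw.mean())
    sd_raw = float(raw.std(ddof=1))
    if sd_raw <= 0:
        raise CFAConvergenceError("degenerate scoring equation: zero score variance")
    return MetSLoadings(
        subgroup=subgroup,
        transforms=tr,
        means={c: float(means[k]) for k, c in enumerate(COMPONENTS)},
        sds={c: float(sds[k]) for k, c in enumerate(COMPONENTS)},
        loadings={c: float(lam[k]) for k, c in enumerate(COMPONENTS)},
        offset=offset,
        scale=1.0 / sd_raw,
        degenerate=degenerate,
        provenance="cfa-fit",
    )


def mets_z(components: Mapping[str, float] | pd.DataFrame, loadings: MetSLoadings):
    """Score participants with a stored MetS severity equation.

    ``components`` is either a single mapping component -> value or a
    DataFrame with the five component columns.  Missing values are refused
    (participants with incomplete components are excluded upstream, not
    imputed).
    """
    if isinstance(components, Mapping) and not isinstance(components, pd.DataFrame):
        frame = pd.DataFrame({c: [components[c]] for c in COMPONENTS if c in components})
        single = True
    else:
        frame = components
        single = False
    missing = [c for c in COMPONENTS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing MetS components: {missing}")
    if frame[list(COMPONENTS)].isna().any().any():
        raise ValueError("missing (NaN) MetS component values; exclude these participants")
    raw = np.zeros(len(frame), dtype=float)
    for c in COMPONENTS:
        z = (_transform(frame[c].to_numpy(), loadings.transforms[c], c) - loadings.means[c]) / loadings.sds[c]
        raw += loadings.loadings[c] * z
    score = loadings.scale * (raw - loadings.offset)
    if single:
        return float(score[0])
    return pd.Series(score, index=frame.index, name="mets_z")


def score_cohort(
    cohort: CohortTable | pd.DataFrame,
    loadings_by_subgroup: Mapping[str, MetSLoadings],
) -> pd.Series:
    """MetS severity Z for every participant, using their subgroup equation."""
    df = cohort.participants if isinstance(cohort, CohortTable) else cohort
    out = pd.Series(np.nan, index=df.index, name="mets_z")
    for sub, grp in df.groupby("subgroup"):
        if sub not in loadings_by_subgroup:
            raise KeyError(f"no loadings for subgroup {sub!r}")
        out.loc[grp.index] = mets_z(grp[list(COMPONENTS)], loadings_by_subgroup[sub]).to_numpy()
    return out


def homa_ir(fasting_insulin, fasting_glucose):
    """HOMA-IR = fasting insulin (mU/L) x fasting glucose (mg/dL) / 405."""
    ins = np.asarray(fasting_insulin, dtype=float)
    glu = np.asarray(fasting_glucose, dtype=float)
    if np.any(ins < 0):
        raise ValueError("fasting insulin must be >= 0")
    if np.any(glu <= 0):
        raise ValueError("fasting glucose must be > 0")
    out = ins * glu / 405.0
    if out.ndim == 0:
        return float(out)
    return out


def save_loadings(loadings: Mapping[str, MetSLoadings], path) -> None:
    """Write a subgroup -> scoring-equation YAML file (lossless round trip)."""
    payload = {sub: eq.to_dict() for sub, eq in loadings.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_loadings(path) -> dict[str, MetSLoadings]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {sub: MetSLoadings.from_dict(d) for sub, d in payload.items()}
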