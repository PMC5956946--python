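"""Added-value statistics at a fixed horizon: c, IDI, continuous NRI, VIF.

All comparisons follow the incremental-prediction convention: an augmented
model (comparator risk score + MetS severity, with or without interaction)
against the base model (score only), evaluated on predicted 10-year risks.

* c-statistic — all-pairs concordance (ties count 1/2); binary CIs by
  DeLong's structural-components estimator, survival CIs by seeded
  bootstrap.  The survival version restricts to usable pairs: the earlier
  subject must be an event within the horizon and strictly earlier.
* discrimination slope / IDI — mean predicted risk in events minus
  non-events; IDI is the difference of slopes, with the standard
  paired-difference (two-sample) variance estimator.
* continuous NRI — event component P(up|event) - P(down|event) plus
  non-event component P(down|non-event) - P(up|non-event); exact ties in
  predicted risk count in neither direction; asymptotic multinomial CIs.
* survival IDI/NRI — event status at the horizon estimated under censoring
  by Kaplan-Meier weighting: subjects censored before the horizon
  contribute their conditional event probability ``1 - S(tau)/S(c)`` (KM
  fitted within each reclassification group for the NRI, overall for the
  slopes).  A complete-case fallback (drop censored-before-horizon) is
  available by flag.  With no censoring before the horizon both reduce
  exactly to the binary statistics on horizon-dichotomised outcomes.
* VIF — 1/(1-R^2) from regressing each covariate on the rest; values above
  10 are flagged as severe collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import TEN_YEARS_DAYS

__all__ = [
    "EstimateCI",
    "NriResult",
    "SurvivalIdiNri",
    "PerformanceReport",
    "c_statistic_binary",
    "c_statistic_survival",
    "discrimination_slope",
    "idi",
    "continuous_nri",
    "survival_idi_nri",
    "vif",
    "performance_report",
]

VIF_SEVERE = 10.0


@dataclass
class EstimateCI:
    value: float
    lower: float | None = None
    upper: float | None = None
    se: float | None = None

    def to_dict(self) -> dict:
        return {"value": self.value, "lower": self.lower, "upper": self.upper, "se": self.se}


@dataclass
class NriResult:
    overall: EstimateCI
    event: EstimateCI
    nonevent: EstimateCI

    def to_dict(self) -> dict:
        return {k: getattr(self, k).to_dict() for k in ("overall", "event", "nonevent")}


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both events and non-events are required")


# ---------------------------------------------------------------------------
# c-statistic, binary (midranks + DeLong)
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def c_statistic_binary(p, y, ci: bool = True, alpha: float = 0.05) -> EstimateCI:
    """Area under the ROC curve with a DeLong confidence interval.

    Equals the all-pairs concordance probability with ties counted 1/2.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=bool)
    _check_two_classes(y)
    pe, pn = p[y], p[~y]
    n1, n0 = len(pe), len(pn)
    r_all = _midranks(p)
    r_e = _midranks(pe)
    r_n = _midranks(pn)
    auc = (r_all[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if not ci:
        return EstimateCI(float(auc))
    v10 = (r_all[y] - r_e) / n0          # structural components, events
    v01 = 1.0 - (r_all[~y] - r_n) / n1   # structural components, non-events
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return EstimateCI(float(auc), max(0.0, auc - z * se), min(1.0, auc + z * se), se)


# ---------------------------------------------------------------------------
# c-statistic, survival (Fenwick-tree pair counting + bootstrap)
# ---------------------------------------------------------------------------

class _Fenwick:
    def __init__(self, n: int):
        self.n = n
        self.tree = np.zeros(n + 1)
        self.total = 0.0

    def add(self, i: int, amount: float = 1.0) -> None:
        self.total += amount
        i += 1
        while i <= self.n:
            self.tree[i] += amount
            i += i & (-i)

    def prefix(self, i: int) -> float:
        """Sum of counts at ranks 0..i (inclusive)."""
        s = 0.0
        i += 1
        while i > 0:
            s += self.tree[i]
            i -= i & (-i)
        return s


def _survival_concordance(times, events, risk, horizon) -> tuple[float, float]:
    """(concordant + ties/2, usable pairs) over usable pairs.

    Usable pair: i an event with ``time_i <= horizon`` and ``time_i <
    time_j``; concordant when ``risk_i > risk_j``.
    """
    order = np.argsort(times, kind="mergesort")
    t, e, r = times[order], events[order], risk[order]
    _, rank = np.unique(r, return_inverse=True)
    nr = rank.max() + 1
    starts = np.flatnonzero(np.r_[True, np.diff(t) != 0])
    bounds = np.r_[starts, len(t)]
    bit = _Fenwick(int(nr))
    conc = 0.0
    pairs = 0.0
    for g in range(len(starts) - 1, -1, -1):
        lo, hi = bounds[g], bounds[g + 1]
        for i in range(lo, hi):
            if e[i] and t[i] <= horizon and bit.total > 0:
                le = bit.prefix(rank[i] - 1) if rank[i] > 0 else 0.0
                eq = bit.prefix(rank[i]) - le
                later = bit.total
                conc += le + 0.5 * eq
                pairs += later
        for i in range(lo, hi):
            bit.add(int(rank[i]))
    return conc, pairs


def c_statistic_survival(
    times,
    events,
    risk,
    horizon: float = TEN_YEARS_DAYS,
    ci: bool = True,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> EstimateCI:
    """Concordance for censored follow-up at a fixed horizon.

    Higher predicted risk for the subject with the earlier observed event
    counts as concordant; ties in predicted risk count 1/2.  The CI is a
    seeded percentile bootstrap over subjects.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    risk = np.asarray(risk, dtype=float)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    conc, pairs = _survival_concordance(times, events, risk, horizon)
    if pairs == 0:
        raise ValueError("no usable pairs (no events before the horizon)")
    value = conc / pairs
    if not ci:
        return EstimateCI(float(value))
    rng = np.random.default_rng(seed)
    n = len(times)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        c_b, p_b = _survival_concordance(times[idx], events[idx], risk[idx], horizon)
        if p_b > 0:
            reps.append(c_b / p_b)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return EstimateCI(float(value), float(lo), float(hi), float(np.std(reps, ddof=1)))


# ---------------------------------------------------------------------------
# discrimination slope, IDI, continuous NRI (binary outcomes)
# ---------------------------------------------------------------------------

def discrimination_slope(p, y) -> float:
    """Mean predicted risk among events minus among non-events."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=bool)
    _check_two_classes(y)
    return float(p[y].mean() - p[~y].mean())


def idi(p_old, p_new, y, ci: bool = True, alpha: float = 0.05) -> EstimateCI:
    """Integrated discrimination improvement: difference of slopes.

    The SE is the standard two-sample estimator on the per-subject risk
    differences ``d = p_new - p_old`` (events vs non-events).
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=bool)
    _check_two_classes(y)
    d = p_new - p_old
    d1, d0 = d[y], d[~y]
    value = float(d1.mean() - d0.mean())
    if not ci:
        return EstimateCI(value)
    var = (np.var(d1, ddof=1) / len(d1) if len(d1) > 1 else 0.0) + (
        np.var(d0, ddof=1) / len(d0) if len(d0) > 1 else 0.0
    )
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    return EstimateCI(value, value - z * se, value + z * se, se)


def continuous_nri(p_old, p_new, y, ci: bool = True, alpha: float = 0.05) -> NriResult:
    """Continuous (category-free) NRI with event/non-event decomposition.

    Exact ties (``p_new == p_old``) count as neither up nor down.  The
    overall NRI is exactly the sum of the two components.  CIs use the
    asymptotic multinomial variance of each proportion difference.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(y, dtype=bool)
    _check_two_classes(y)
    up = p_new > p_old
    down = p_new < p_old
    n1 = int(y.sum())
    n0 = int((~y).sum())
    pu, pdn = up[y].mean(), down[y].mean()
    qd, qu = down[~y].mean(), up[~y].mean()
    ev = float(pu - pdn)
    ne = float(qd - qu)
    overall = ev + ne
    if not ci:
        return NriResult(EstimateCI(overall), EstimateCI(ev), EstimateCI(ne))
    var_e = (pu + pdn - (pu - pdn) ** 2) / n1
    var_n = (qd + qu - (qd - qu) ** 2) / n0
    z = stats.norm.ppf(1 - alpha / 2)

    def _ci(v, var):
        se = float(np.sqrt(var))
        return EstimateCI(v, v - z * se, v + z * se, se)

    return NriResult(_ci(overall, var_e + var_n), _ci(ev, var_e), _ci(ne, var_n))


# ---------------------------------------------------------------------------
# survival IDI / NRI at a fixed horizon (KM weighting)
# ---------------------------------------------------------------------------

def _km_event_weights(times, events, horizon) -> np.ndarray:
    """Per-subject probability of an event by the horizon.

    1 for events within the horizon, 0 for subjects followed past it, and
    the Kaplan-Meier conditional probability ``1 - S(tau)/S(c)`` for
    subjects censored at ``c < tau``.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    w = np.zeros(len(times))
    w[events & (times <= horizon)] = 1.0
    frac = ~events & (times < horizon)
    if frac.any():
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        s_tau = float(kmf.predict(horizon))
        s_c = kmf.predict(times[frac]).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(s_c > 0, 1.0 - s_tau / s_c, 1.0)
        w[frac] = np.clip(cond, 0.0, 1.0)
    return w


@dataclass
class SurvivalIdiNri:
    idi: EstimateCI
    nri: NriResult
    slope_old: float
    slope_new: float
    method: str
    horizon: float
    prob_event: float

    def to_dict(self) -> dict:
        return {
            "idi": self.idi.to_dict(),
            "nri": self.nri.to_dict(),
            "slope_old": self.slope_old,
            "slope_new": self.slope_new,
            "method": self.method,
            "horizon": self.horizon,
            "prob_event": self.prob_event,
        }


def _survival_idi_nri_point(times, events, p_old, p_new, horizon, method):
    if method == "complete_case":
        keep = (events & (times <= horizon)) | (times >= horizon)
        if not keep.any():
            raise ValueError("all subjects censored before the horizon")
        y = events[keep] & (times[keep] <= horizon)
        _check_two_classes(y)
        i = idi(p_old[keep], p_new[keep], y, ci=False)
        n = continuous_nri(p_old[keep], p_new[keep], y, ci=False)
        sl_o = discrimination_slope(p_old[keep], y)
        sl_n = discrimination_slope(p_new[keep], y)
        return i.value, n, sl_o, sl_n, float(y.mean())

    # KM-weighted construction
    if not np.any(events & (times <= horizon)) and not np.any(times >= horizon):
        raise ValueError("all subjects censored before the horizon")
    up = p_new > p_old
    down = p_new < p_old
    tie = ~up & ~down
    n = len(times)
    p_g = {}
    e_g = {}
    for label, sel in (("up", up), ("down", down), ("tie", tie)):
        p_g[label] = sel.mean()
        e_g[label] = float(_km_event_weights(times[sel], events[sel], horizon).mean()) if sel.any() else 0.0
    pe = sum(p_g[g] * e_g[g] for g in p_g)
    if pe <= 0 or pe >= 1:
        raise ValueError("degenerate horizon event probability")
    ev = (p_g["up"] * e_g["up"] - p_g["down"] * e_g["down"]) / pe
    ne = (p_g["down"] * (1 - e_g["down"]) - p_g["up"] * (1 - e_g["up"])) / (1 - pe)
    nri = NriResult(EstimateCI(float(ev + ne)), EstimateCI(float(ev)), EstimateCI(float(ne)))

    w = _km_event_weights(times, events, horizon)
    sw = w.sum()
    swc = (1 - w).sum()

    def slope(p):
        return float((w * p).sum() / sw - ((1 - w) * p).sum() / swc)

    sl_o, sl_n = slope(p_old), slope(p_new)
    return sl_n - sl_o, nri, sl_o, sl_n, float(pe)


def survival_idi_nri(
    times,
    events,
    p_old,
    p_new,
    horizon: float = TEN_YEARS_DAYS,
    method: str = "km",
    ci: bool = False,
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> SurvivalIdiNri:
    """IDI and continuous NRI for censored follow-up at a fixed horizon.

    ``method="km"`` (default) uses Kaplan-Meier event-probability weighting
    within reclassification groups; ``method="complete_case"`` drops
    subjects censored before the horizon.  CIs, when requested, are a
    seeded percentile bootstrap.
    """
    if method not in ("km", "complete_case"):
        raise ValueError(f"unknown method {method!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    i_val, nri, sl_o, sl_n, pe = _survival_idi_nri_point(times, events, p_old, p_new, horizon, method)
    if not ci:
        return SurvivalIdiNri(EstimateCI(float(i_val)), nri, sl_o, sl_n, method, horizon, pe)
    rng = np.random.default_rng(seed)
    n = len(times)
    reps = {"idi": [], "overall": [], "event": [], "nonevent": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            i_b, nri_b, *_ = _survival_idi_nri_point(
                times[idx], events[idx], p_old[idx], p_new[idx], horizon, method
            )
        except ValueError:
            continue
        reps["idi"].append(i_b)
        reps["overall"].append(nri_b.overall.value)
        reps["event"].append(nri_b.event.value)
        reps["nonevent"].append(nri_b.nonevent.value)

    def _boot_ci(value, arr):
        lo, hi = np.percentile(arr, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return EstimateCI(float(value), float(lo), float(hi), float(np.std(arr, ddof=1)))

    return SurvivalIdiNri(
        _boot_ci(i_val, reps["idi"]),
        NriResult(
            _boot_ci(nri.overall.value, reps["overall"]),
            _boot_ci(nri.event.value, reps["event"]),
            _boot_ci(nri.nonevent.value, reps["nonevent"]),
        ),
        sl_o,
        sl_n,
        method,
        horizon,
        pe,
    )


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate, ``1 / (1 - R_j^2)``.

    Each covariate is regressed (with intercept) on all the others; rank
    deficiency yields an infinite VIF.  Values above 10 indicate severe
    collinearity.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        sst = float(((yj - yj.mean()) ** 2).sum())
        if sst == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float((resid**2).sum()) / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    """Incremental-value statistics for one nested comparison at a horizon."""

    comparison: str  # "C vs A" or "D vs A"
    outcome_family: str
    horizon: float
    c_old: EstimateCI
    c_new: EstimateCI
    delta_c: float
    slope_old: float
    slope_new: float
    idi: EstimateCI
    nri: NriResult
    aic: dict[str, float]
    vifs: dict[str, float]
    n: int
    method: str = "binary"

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "outcome_family": self.outcome_family,
            "horizon": self.horizon,
            "c_old": self.c_old.to_dict(),
            "c_new": self.c_new.to_dict(),
            "delta_c": self.delta_c,
            "slope_old": self.slope_old,
            "slope_new": self.slope_new,
            "idi": self.idi.to_dict(),
            "nri": self.nri.to_dict(),
            "aic": self.aic,
            "vifs": {k: (None if np.isinf(v) else v) for k, v in self.vifs.items()},
            "n": self.n,
            "method": self.method,
        }


def performance_report(
    nested,
    new_model: str = "C",
    horizon_days: float = TEN_YEARS_DAYS,
    km_method: str = "km",
    n_boot: int = 200,
    seed: int = 0,
) -> PerformanceReport:
    """Assemble the added-value statistics for ``new_model`` vs Model A."""
    p_old = nested.predicted_risks("A", horizon_days)
    p_new = nested.predicted_risks(new_model, horizon_days)
    data = nested.data
    aic = {m: f.aic for m, f in nested.fits.items()}
    vif_design = data[[nested.score_col, nested.mets_col] + nested.adjust_cols]
    vifs = vif(vif_design).to_dict()

    if nested.outcome_family == "logistic":
        y = data[nested.t2dm_col].to_numpy(dtype=bool)
        c_old = c_statistic_binary(p_old, y)
        c_new = c_statistic_binary(p_new, y)
        sl_o = discrimination_slope(p_old, y)
        sl_n = discrimination_slope(p_new, y)
        i = idi(p_old, p_new, y)
        nri = continuous_nri(p_old, p_new, y)
        method = "binary"
    else:
        t = data[nested.duration_col].to_numpy(dtype=float)
        e = data[nested.event_col].to_numpy(dtype=bool)
        c_old = c_statistic_survival(t, e, p_old, horizon_days, n_boot=n_boot, seed=seed)
        c_new = c_statistic_survival(t, e, p_new, horizon_days, n_boot=n_boot, seed=seed + 1)
        rep = survival_idi_nri(t, e, p_old, p_new, horizon_days, method=km_method, ci=True, n_boot=n_boot, seed=seed + 2)
        sl_o, sl_n = rep.slope_old, rep.slope_new
        i = rep.idi
        nri = rep.nri
        method = f"survival-{km_method}"
    return PerformanceReport(
        comparison=f"{new_model} vs A",
        outcome_family=nested.outcome_family,
        horizon=horizon_days,
        c_old=c_old,
        c_new=c_new,
        delta_c=float(c_new.value - c_old.value),
        slope_old=sl_o,
        slope_new=sl_n,
        idi=i,
        nri=nri,
        aic=aic,
        vifs=vifs,
        n=len(data),
        method=method,
    )
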