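"""Nested Model A-D fitting: Cox PH for time-to-CHD, logistic for T2DM.

The four-model ladder mirrors the incremental-value design: Model A is the
comparator risk score alone, Model B the MetS severity score alone, Model C
both, and Model D adds their interaction; every model adjusts for study site
through fixed-effect indicator columns (first site as reference).

Cox models are fitted by an in-repo vectorized Newton maximiser of the
partial likelihood with Efron tie handling by default (day-resolution data
produce ties) and Breslow available by flag; predicted 10-year risks use the
Breslow baseline cumulative hazard, ``1 - exp(-H0(t) * exp(x'beta))``.
Logistic models delegate to statsmodels.  Both report Wald 95% CIs on the
hazard/odds-ratio scale and ``AIC = 2k - 2 logL`` (partial likelihood for
Cox).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_cohort import TEN_YEARS_DAYS

__all__ = [
    "ModelFit",
    "NestedComparison",
    "ConvergenceError",
    "fit_cox",
    "fit_logistic",
    "run_nested",
    "site_dummies",
]


class ConvergenceError(RuntimeError):
    """Non-convergence, rank deficiency, monotone likelihood or separation."""


@dataclass
class ModelFit:
    """A fitted Cox or logistic model with Wald inference.

    ``params``/``cov`` are indexed by term name; ``loglik`` is the partial
    log-likelihood for Cox fits.  ``baseline_cumhaz`` holds the Breslow
    estimate (event time -> H0) for Cox fits so 10-year risks can be
    reconstructed.
    """

    outcome_family: str  # "cox" | "logistic"
    terms: list[str]
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    ties: str | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    baseline_cumhaz: pd.Series | None = None
    _train_lp: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def wald_p(self, term: str) -> float:
        z = self.params[term] / self.se[term]
        return float(2.0 * stats.norm.sf(abs(z)))

    def ratio_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """HR (Cox) or OR (logistic) with Wald CIs per term."""
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.se
        est = np.exp(self.params)
        label = "HR" if self.outcome_family == "cox" else "OR"
        return pd.DataFrame(
            {
                "coef": self.params,
                label: est,
                f"{label}_lower": np.exp(self.params - z * se),
                f"{label}_upper": np.exp(self.params + z * se),
                "p": [self.wald_p(t) for t in self.params.index],
            }
        )

    # -- predictions --------------------------------------------------------
    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.terms].to_numpy(dtype=float)
        return X @ self.params.to_numpy()

    def predict_risk(self, df: pd.DataFrame, horizon_days: float = TEN_YEARS_DAYS) -> np.ndarray:
        """Predicted event probability by the horizon (fitted scale)."""
        if self.outcome_family == "logistic":
            from scipy.special import expit

            cols = [c for c in self.terms if c != "_intercept"]
            lp = df[cols].to_numpy(dtype=float) @ self.params[cols].to_numpy()
            if "_intercept" in self.params.index:
                lp = lp + self.params["_intercept"]
            return expit(lp)
        lp = self.linear_predictor(df)
        h0 = self._h0_at(horizon_days)
        return 1.0 - np.exp(-h0 * np.exp(lp))

    def _h0_at(self, t: float) -> float:
        if self.baseline_cumhaz is None:
            raise ValueError("no baseline hazard stored for this fit")
        ch = self.baseline_cumhaz
        sel = ch.index.to_numpy() <= t
        return float(ch.to_numpy()[sel][-1]) if sel.any() else 0.0


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron / Breslow), Newton-Raphson
# ---------------------------------------------------------------------------

def _cox_quantities(beta, X, order, group_starts, group_sizes, event_groups, ties):
    """Partial logL, gradient, Hessian for sorted data.

    Data are sorted by ascending time; ``group_starts``/``group_sizes``
    delimit tied-time groups; ``event_groups`` maps group -> indices (into
    the sorted arrays) of events in that group.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; cancels in all ratios and logs
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix sums over the ascending-time order
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wX[::-1], axis=0)[::-1]
    s2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    logL = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # degenerate denominators (underflowed risk sets on a diverging path)
    # surface as non-finite values handled by the caller
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for gs, dsel in event_groups:
            d = len(dsel)
            r0, r1, r2 = s0[gs], s1[gs], s2[gs]
            g0 = w[dsel].sum()
            g1 = wX[dsel].sum(axis=0)
            g2 = wXX[dsel].sum(axis=0)
            logL += eta[dsel].sum()
            grad += X[dsel].sum(axis=0)
            fracs = (np.arange(d) / d) if ties == "efron" else np.zeros(d)
            for frac in fracs:
                d0 = r0 - frac * g0
                d1 = r1 - frac * g1
                d2 = r2 - frac * g2
                logL -= np.log(d0)
                grad -= d1 / d0
                hess -= d2 / d0 - np.outer(d1, d1) / d0**2
    return logL, grad, hess


def _prepare_cox(time, event):
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    # tied-time groups
    starts = np.flatnonzero(np.r_[True, np.diff(t_sorted) != 0])
    sizes = np.diff(np.r_[starts, len(t_sorted)])
    event_groups = []
    for gs, sz in zip(starts, sizes):
        dsel = gs + np.flatnonzero(e_sorted[gs : gs + sz])
        if len(dsel):
            event_groups.append((gs, dsel))
    return order, starts, sizes, event_groups


def fit_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 60,
) -> ModelFit:
    """Maximise the Cox partial likelihood by Newton-Raphson.

    Raises :class:`ConvergenceError` on rank-deficient designs, monotone
    likelihood (coefficients diverging), or failure to reach a gradient
    max-norm below ``tol``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    covariates = list(covariates)
    X = df[covariates].to_numpy(dtype=float)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=bool)
    if np.any(time <= 0):
        raise ValueError("durations must be positive")
    n, p = X.shape
    Xc = X - X.mean(axis=0)  # centering improves conditioning; beta unchanged
    if np.linalg.matrix_rank(Xc) < p:
        raise ConvergenceError("rank-deficient design (degenerate or collinear covariate)")
    order, starts, sizes, event_groups = _prepare_cox(time, event)
    Xs = Xc[order]

    beta = np.zeros(p)
    logL, grad, hess = _cox_quantities(beta, Xs, order, starts, sizes, event_groups, ties)
    flags: list[str] = []
    converged = False
    # gradient is a sum over events, so the tolerance is per event
    gscale = max(1.0, float(event.sum()))
    noise = 1e-13 * max(1.0, abs(logL))
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol * gscale:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # Newton decrement g'H^{-1}g: expected logL gain of the full step;
        # once it is below the float noise of logL the maximum is reached
        noise = 1e-13 * max(1.0, abs(logL))
        if 0.0 <= float(grad @ step) < noise:
            converged = True
            break
        new_beta = beta + step
        new = _cox_quantities(new_beta, Xs, order, starts, sizes, event_groups, ties)
        halving = 0
        while (not np.isfinite(new[0]) or new[0] < logL - noise) and halving < 30:
            step /= 2.0
            new_beta = beta + step
            new = _cox_quantities(new_beta, Xs, order, starts, sizes, event_groups, ties)
            halving += 1
        if not (np.isfinite(new[0]) and np.all(np.isfinite(new[1]))):
            raise ConvergenceError(
                "monotone partial likelihood: the likelihood is unbounded "
                "(a covariate may perfectly separate event order)"
            )
        beta = new_beta
        logL, grad, hess = new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "monotone partial likelihood: a coefficient is diverging "
                "(a covariate may perfectly separate event order)"
            )
    else:
        if np.max(np.abs(grad)) < tol * gscale:
            converged = True
    if not converged:
        raise ConvergenceError(f"Newton iteration did not reach tolerance {tol}")

    info = -hess
    cov = np.linalg.inv(info)
    params = pd.Series(beta, index=covariates)
    # Breslow baseline cumulative hazard on the uncentered scale
    lp_raw = X @ beta
    off = float(X.mean(axis=0) @ beta)  # lp_centered = lp_raw - off
    w = np.exp(lp_raw[order] - off)
    s0 = np.cumsum(w[::-1])[::-1]
    increments = {}
    for gs, dsel in event_groups:
        t = time[order][gs]
        increments[t] = len(dsel) / s0[gs]
    ch = pd.Series(increments).sort_index().cumsum()
    ch = ch * np.exp(-off)  # so that H(t|x) = H0(t) * exp(x'beta) with raw x
    return ModelFit(
        outcome_family="cox",
        terms=covariates,
        params=params,
        cov=pd.DataFrame(cov, index=covariates, columns=covariates),
        loglik=float(logL),
        n=n,
        n_events=int(event.sum()),
        ties=ties,
        converged=converged,
        flags=flags,
        baseline_cumhaz=ch,
        _train_lp=lp_raw,
    )


# ---------------------------------------------------------------------------
# logistic regression (statsmodels backend)
# ---------------------------------------------------------------------------

def fit_logistic(
    df: pd.DataFrame,
    outcome_col: str,
    covariates: Sequence[str],
    add_intercept: bool = True,
) -> ModelFit:
    """Logistic fit via iteratively reweighted least squares (statsmodels)."""
    covariates = list(covariates)
    X = df[covariates].to_numpy(dtype=float)
    y = df[outcome_col].to_numpy(dtype=float)
    names = list(covariates)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["_intercept"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConvergenceError("rank-deficient design (degenerate or collinear covariate)")
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    for wmsg in caught:
        if "separat" in str(wmsg.message).lower():
            flags.append("possible perfect separation")
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge")
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    fit = ModelFit(
        outcome_family="logistic",
        terms=names,
        params=params,
        cov=cov,
        loglik=float(res.llf),
        n=len(y),
        n_events=int(y.sum()),
        converged=True,
        flags=flags,
    )
    return fit


# ---------------------------------------------------------------------------
# nested comparisons
# ---------------------------------------------------------------------------

def site_dummies(df: pd.DataFrame, site_col: str = "site") -> pd.DataFrame:
    """Fixed-effect site indicators, first site (sorted) as reference."""
    sites = sorted(df[site_col].unique())
    return pd.DataFrame(
        {f"site_{s}": (df[site_col] == s).astype(float) for s in sites[1:]}, index=df.index
    )


@dataclass
class NestedComparison:
    """Models A-D on one analytic sample.

    ``fits`` are on the scores' original scale (used for predicted risks and
    AIC); ``display_fits`` refit A/C/D with the standardised score so HRs/ORs
    are per comparator-score SD, matching the MetS severity unit.  The
    partial/likelihoods of the two parametrisations agree (affine
    invariance).
    """

    outcome_family: str
    fits: dict[str, ModelFit]
    display_fits: dict[str, ModelFit]
    interaction_p: float
    score_col: str
    mets_col: str
    adjust_cols: list[str]
    data: pd.DataFrame
    interaction_form: str = "continuous"
    duration_col: str = "time_to_chd"
    event_col: str = "chd_event"
    t2dm_col: str = "t2dm_10y"

    def predicted_risks(self, model: str, horizon_days: float = TEN_YEARS_DAYS) -> np.ndarray:
        return self.fits[model].predict_risk(self.data, horizon_days)


def _interaction_column(df, score_col, mets_col, form):
    if form == "continuous":
        return df[score_col] * df[mets_col]
    if form == "quintile_index":
        from .interaction_report import quintile_bins

        q, _, degenerate = quintile_bins(df[score_col].to_numpy())
        if degenerate:
            raise ValueError("degenerate quintiles for interaction term")
        return pd.Series(q, index=df.index, dtype=float) * df[mets_col]
    raise ValueError(f"unknown interaction form {form!r}")


def run_nested(
    df: pd.DataFrame,
    score_col: str,
    mets_col: str,
    outcome: str,
    duration_col: str = "time_to_chd",
    event_col: str = "chd_event",
    t2dm_col: str = "t2dm_10y",
    site_col: str = "site",
    score_std_col: str | None = None,
    ties: str = "efron",
    interaction_form: str = "continuous",
) -> NestedComparison:
    """Fit the Model A-D ladder with site adjustment on one sample.

    ``outcome`` is ``"chd"`` (Cox) or ``"t2dm"`` (logistic).  When
    ``score_std_col`` is given, display fits use it so ratio tables are per
    SD; prediction-oriented fits always use ``score_col`` (original scale).
    """
    if outcome not in ("chd", "t2dm"):
        raise ValueError(f"unknown outcome {outcome!r}")
    work = df.copy()
    sites = site_dummies(work, site_col)
    work = pd.concat([work, sites], axis=1)
    adjust = list(sites.columns)

    inter = _interaction_column(work, score_col, mets_col, interaction_form)
    work["_interaction"] = inter

    def _fit(cols: list[str]) -> ModelFit:
        try:
            if outcome == "chd":
                return fit_cox(work, duration_col, event_col, cols, ties=ties)
            return fit_logistic(work, t2dm_col, cols)
        except ConvergenceError as exc:
            raise ConvergenceError(f"{exc} [model terms: {cols}]") from exc

    fits = {
        "A": _fit([score_col] + adjust),
        "B": _fit([mets_col] + adjust),
        "C": _fit([score_col, mets_col] + adjust),
        "D": _fit([score_col, mets_col, "_interaction"] + adjust),
    }
    display_fits = dict(fits)
    if score_std_col is not None and score_std_col != score_col:
        saved = work["_interaction"].copy()
        work["_interaction"] = _interaction_column(work, score_std_col, mets_col, interaction_form)
        display_fits = {
            "A": _fit([score_std_col] + adjust),
            "B": fits["B"],
            "C": _fit([score_std_col, mets_col] + adjust),
            "D": _fit([score_std_col, mets_col, "_interaction"] + adjust),
        }
        work["_interaction"] = saved
    interaction_p = fits["D"].wald_p("_interaction")
    return NestedComparison(
        outcome_family="cox" if outcome == "chd" else "logistic",
        fits=fits,
        display_fits=display_fits,
        interaction_p=interaction_p,
        score_col=score_col,
        mets_col=mets_col,
        adjust_cols=adjust,
        data=work,
        interaction_form=interaction_form,
        duration_col=duration_col,
        event_col=event_col,
        t2dm_col=t2dm_col,
    )
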