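"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (O(n^2) pair loops, explicit formula
summation, closed forms) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import numpy as np


# -- concordance -------------------------------------------------------------

def auc_pairs(p, y):
    """All-pairs AUC with ties counted 1/2 (O(n^2))."""
    p = np.asarray(p, float)
    y = np.asarray(y, bool)
    num = 0.0
    den = 0
    for pe in p[y]:
        for pn in p[~y]:
            den += 1
            if pe > pn:
                num += 1.0
            elif pe == pn:
                num += 0.5
    return num / den


def survival_concordance_pairs(times, events, risk, horizon):
    """Usable-pair survival concordance by exhaustive enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    risk = np.asarray(risk, float)
    num = 0.0
    den = 0
    n = len(times)
    for i in range(n):
        if not events[i] or times[i] > horizon:
            continue
        for j in range(n):
            if times[j] <= times[i]:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


# -- slopes / IDI / NRI ------------------------------------------------------

def slope_direct(p, y):
    p = np.asarray(p, float)
    y = np.asarray(y, bool)
    return p[y].mean() - p[~y].mean()


def idi_direct(p_old, p_new, y):
    return slope_direct(p_new, y) - slope_direct(p_old, y)


def nri_counts(p_old, p_new, y):
    """(overall, event, non-event) by explicit sign counting."""
    p_old = np.asarray(p_old, float)
    p_new = np.asarray(p_new, float)
    y = np.asarray(y, bool)
    up_e = down_e = up_n = down_n = 0
    for po, pn, yi in zip(p_old, p_new, y):
        if pn > po:
            if yi:
                up_e += 1
            else:
                up_n += 1
        elif pn < po:
            if yi:
                down_e += 1
            else:
                down_n += 1
    n1 = int(y.sum())
    n0 = len(y) - n1
    ev = (up_e - down_e) / n1
    ne = (down_n - up_n) / n0
    return ev + ne, ev, ne


# -- collinearity ------------------------------------------------------------

def vif_from_corr(X):
    """VIF via the diagonal of the inverse correlation matrix."""
    X = np.asarray(X, float)
    R = np.corrcoef(X, rowvar=False)
    return np.diag(np.linalg.inv(R))


# -- Cox partial likelihood --------------------------------------------------

def cox_loglik_direct(beta, X, times, events, ties="efron"):
    """Partial log-likelihood by explicit risk-set enumeration."""
    beta = np.asarray(beta, float)
    X = np.asarray(X, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    eta = X @ beta
    w = np.exp(eta)
    logL = 0.0
    for t in np.unique(times[events]):
        D = np.flatnonzero(events & (times == t))
        R = np.flatnonzero(times >= t)
        d = len(D)
        s0 = w[R].sum()
        g0 = w[D].sum()
        logL += eta[D].sum()
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            logL -= np.log(s0 - frac * g0)
    return logL


def logistic_loglik_direct(beta, X, y):
    """Bernoulli log-likelihood by direct summation (X includes intercept)."""
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = np.asarray(y, float)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


# -- generative closed forms -------------------------------------------------

def weibull_survival(t_years, shape, scale_years, lp=0.0):
    return np.exp(-((t_years / scale_years) ** shape) * np.exp(lp))


def one_factor_correlation(loadings):
    """Implied correlation matrix of a unit-variance one-factor model."""
    lam = np.asarray(loadings, float)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R
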