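"""Naive from-scratch reference implementations used as oracles in tests.

Everything here is deliberately written the slow, direct way — explicit
loops over event times and candidate tuples, scipy/statsmodels fits per
tuple — and shares no code with the package's vectorized prefix-sum
kernels, so agreement between the two is a meaningful check of the search.
"""

from __future__ import annotations

import itertools

import numpy as np
import statsmodels.api as sm


def naive_groups(z, cuts):
    """Group by explicit comparison: value equal to a cut joins the upper group."""
    z = np.asarray(z, dtype=float)
    return np.array([sum(v >= c for c in cuts) for v in z], dtype=int)


def naive_logrank(group, time, event):
    """K-sample log-rank from the risk-table recursion at each event time."""
    group = np.asarray(group)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.unique(group)
    G = len(labels)
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        n_t = at_risk.sum()
        d_t = dead.sum()
        n_g = np.array([(at_risk & (group == g)).sum() for g in labels], dtype=float)
        d_g = np.array([(dead & (group == g)).sum() for g in labels], dtype=float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            c = d_t * (n_t - d_t) / (n_t - 1)
            for a in range(G):
                for b in range(G):
                    V[a, b] += c * ((a == b) * n_g[a] / n_t - n_g[a] * n_g[b] / n_t**2)
    u = (O - E)[:-1]
    return float(u @ np.linalg.solve(V[:-1, :-1], u))


def naive_cox_loglik(beta, X, time, event):
    """Efron log partial likelihood evaluated directly."""
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(dead.sum())
        sw = w[at_risk].sum()
        dw = w[dead].sum()
        ll += eta[dead].sum()
        for el in range(d):
            ll -= np.log(sw - (el / d) * dw)
    return float(ll)


def naive_cox_fit(X, time, event, max_iter=50, tol=1e-10):
    """Newton maximization of the Efron partial likelihood (analytic
    gradient/Hessian assembled time-by-time)."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    p = X.shape[1]
    beta = np.zeros(p)
    ll0 = naive_cox_loglik(beta, X, time, event)
    ll = ll0
    times = np.unique(time[event == 1])
    masks = [((time == t) & (event == 1), time >= t) for t in times]
    for _ in range(max_iter):
        w = np.exp(X @ beta)
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for dead, at_risk in masks:
            d = int(dead.sum())
            Xr, wr = X[at_risk], w[at_risk]
            Xd, wd = X[dead], w[dead]
            s0r, s1r = wr.sum(), wr @ Xr
            s2r = (wr[:, None] * Xr).T @ Xr
            s0d, s1d = wd.sum(), wd @ Xd
            s2d = (wd[:, None] * Xd).T @ Xd
            grad += Xd.sum(axis=0)
            for el in range(d):
                f = el / d
                s0 = s0r - f * s0d
                s1 = s1r - f * s1d
                s2 = s2r - f * s2d
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1, s1) / s0**2
        if np.max(np.abs(grad)) < tol:
            break
        step = np.linalg.solve(-hess, grad)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = naive_cox_loglik(cand, X, time, event)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll = cand, ll_new
    converged = bool(np.max(np.abs(beta)) < 15)
    return beta, ll, ll0, converged


def naive_cox_lrt(group, time, event, k):
    X = np.column_stack([(np.asarray(group) >= j).astype(float) for j in range(1, k + 1)])
    beta, ll, ll0, converged = naive_cox_fit(X, time, event)
    return 2.0 * (ll - ll0), converged


def naive_logistic_lrt(group, y, k):
    """LRT of the grouped logistic model via an independent statsmodels fit."""
    X = sm.add_constant(
        np.column_stack([(np.asarray(group) >= j).astype(float) for j in range(1, k + 1)])
    )
    res = sm.Logit(np.asarray(y, dtype=int), X).fit(disp=0)
    return 2.0 * (res.llf - res.llnull)


def naive_auc(score, y):
    """Pairwise Mann-Whitney brute force: wins + half-ties over all
    (positive, negative) pairs."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=int)
    pos = score[y == 1]
    neg = score[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_chi2(group, y):
    group = np.asarray(group)
    y = np.asarray(y, dtype=int)
    labels = np.unique(group)
    obs = np.array([[((group == g) & (y == c)).sum() for c in (0, 1)] for g in labels],
                   dtype=float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def _tuple_valid(group, k, min_size, min_events=None, event=None, y=None,
                 criterion=None):
    counts = np.array([(group == g).sum() for g in range(k + 1)])
    if (counts < min_size).any():
        return False
    if event is not None and min_events is not None:
        ev = np.array([event[group == g].sum() for g in range(k + 1)])
        if (ev < min_events).any():
            return False
    if criterion == "logistic_lrt" and y is not None:
        ev = np.array([y[group == g].sum() for g in range(k + 1)])
        if ((ev == 0) | (ev == counts)).any():
            return False
    return True


def naive_search(z, outcome, k, criterion, candidates, min_size, min_events=5):
    """Double-loop exhaustive reference search.

    ``outcome`` is (time, event) for survival criteria or y for binary ones.
    Returns (best_cuts, best_value); ties keep the first (lexicographically
    smallest) tuple.
    """
    z = np.asarray(z, dtype=float)
    best_cuts, best_value = None, -np.inf
    survival = criterion in ("logrank", "cox_lrt")
    if survival:
        time, event = outcome
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        y = None
    else:
        y = np.asarray(outcome, int)
        time = event = None
    for cuts in itertools.combinations(sorted(candidates), k):
        group = naive_groups(z, cuts)
        if survival:
            if not _tuple_valid(group, k, min_size, min_events, event=event):
                continue
        else:
            if not _tuple_valid(group, k, min_size, y=y, criterion=criterion):
                continue
        if criterion == "logrank":
            value = naive_logrank(group, time, event)
        elif criterion == "cox_lrt":
            value, converged = naive_cox_lrt(group, time, event, k)
            if not converged:
                continue
        elif criterion == "logistic_lrt":
            value = naive_logistic_lrt(group, y, k)
        elif criterion == "max_auc":
            frac = np.array([y[group == g].mean() for g in range(k + 1)])
            value = naive_auc(frac[group], y)
        elif criterion == "chi2":
            value = naive_chi2(group, y)
        else:
            raise ValueError(criterion)
        if value > best_value + 1e-12:
            best_cuts, best_value = cuts, value
    return best_cuts, best_value
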