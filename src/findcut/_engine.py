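"""Vectorized criterion kernels for the exhaustive cutpoint scan.

The search evaluates a test statistic (or AUC) for every candidate cutpoint
tuple.  Because candidates are thresholds on a single sorted axis, every
group count needed by the statistics is a *prefix* quantity: with subjects
sorted by z, the risk set and death count of the group below a cut are
cumulative sums evaluated at the cut's rank.  All criteria are therefore
computed from a handful of prefix arrays:

* log-rank (1 or 2 cuts): observed-minus-expected and the hypergeometric
  covariance reduce to linear and bilinear forms in the prefix at-risk
  matrix; the 2-cut scan needs one matrix product.
* Cox LRT: a dedicated Newton solver for the Efron partial likelihood on a
  *grouped* covariate (group-level risk/death counts per event time), run
  per tuple.
* logistic LRT, Pearson chi-square, AUC: closed forms in the per-group
  subject and event counts (the unadjusted logistic model is saturated in
  the groups).

Tuples are enumerated in lexicographic order and the argmax takes the first
maximal entry, so ties break toward the smallest cutpoints deterministically.

These kernels are private; :mod:`findcut.search` is the public surface.
They are cross-checked in the test suite against lifelines, statsmodels,
scipy and a naive per-tuple reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

__all__ = [
    "ScanOutput",
    "SurvivalData",
    "BinaryData",
    "scan_survival",
    "scan_binary",
    "cox_grouped_fit",
    "cox_score_statistic",
    "null_partial_loglik",
    "grouped_auc",
]

_SINGULAR_TOL = 1e-10


@dataclass
class ScanOutput:
    """Criterion values over every enumerated cutpoint tuple."""

    cut_indices: np.ndarray  # (n_tuples, K) indices into the candidate values
    values: np.ndarray  # criterion value per tuple (nan where invalid)
    valid: np.ndarray  # bool mask of tuples satisfying constraints + fit ok
    df: int  # chi-square df of the criterion (0 for AUC)

    @property
    def n_evaluated(self) -> int:
        return len(self.values)

    @property
    def n_invalid(self) -> int:
        return int((~self.valid).sum())

    def best_index(self) -> int:
        """First (lexicographically smallest) tuple attaining the max."""
        if not self.valid.any():
            return -1
        vals = np.where(self.valid, self.values, -np.inf)
        return int(np.argmax(vals))


# ---------------------------------------------------------------------------
# prefix structures


class SurvivalData:
    """Prefix risk/death tables of a survival cohort sorted by z."""

    def __init__(self, z, time, event, cut_values):
        z = np.asarray(z, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        order = np.argsort(z, kind="stable")
        self.n = len(z)
        self.z_sorted = z[order]
        tz, ez = time[order], event[order]
        self.cut_values = np.asarray(cut_values, dtype=float)
        # prefix rank of each cut: size of the group strictly below it
        self.p = np.searchsorted(self.z_sorted, self.cut_values, side="left")
        self.ts = np.unique(tz[ez == 1])  # distinct event times
        d = len(self.ts)
        at_risk = tz[None, :] >= self.ts[:, None]  # (d, n)
        deaths = (tz[None, :] == self.ts[:, None]) & (ez[None, :] == 1)
        Ncum = np.concatenate(
            [np.zeros((d, 1)), np.cumsum(at_risk, axis=1)], axis=1
        )
        Dcum = np.concatenate(
            [np.zeros((d, 1)), np.cumsum(deaths, axis=1)], axis=1
        )
        self.n_t = Ncum[:, -1]  # total at risk per event time
        self.d_t = Dcum[:, -1]  # total deaths per event time
        self.N = Ncum[:, self.p]  # (d, m) at-risk below each cut
        self.D = Dcum[:, self.p]  # (d, m) deaths below each cut
        evcum = np.concatenate([[0], np.cumsum(ez)])
        self.ev = evcum[self.p].astype(float)  # events strictly below each cut
        self.total_events = float(evcum[-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            c = self.d_t * (self.n_t - self.d_t) / (self.n_t - 1)
        self.c_t = np.where(self.n_t > 1, c, 0.0)
        # expanded Efron tie representation: one row per (event time, l)
        reps = self.d_t.astype(int)
        self.jj = np.repeat(np.arange(d), reps)
        self.frac = np.concatenate(
            [np.arange(k) / k for k in reps if k > 0]
        ) if reps.sum() else np.zeros(0)
        # linear-form coefficients for the log-rank pieces
        with np.errstate(divide="ignore", invalid="ignore"):
            dn = np.where(self.n_t > 0, self.d_t / self.n_t, 0.0)
            cn = np.where(self.n_t > 0, self.c_t / self.n_t, 0.0)
        self.E_lin = dn @ self.N  # expected deaths below each cut
        self.S_lin = cn @ self.N  # sum c_t * N / n_t
        sq = np.sqrt(self.c_t)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(self.n_t > 0, sq / self.n_t, 0.0)
        self._C = self.N * w[:, None]  # for the bilinear form
        self._G = None

    @property
    def m(self) -> int:
        return len(self.cut_values)

    @property
    def G(self) -> np.ndarray:
        """Bilinear form G[i,j] = sum_t c_t N_i N_j / n_t**2 (lazy matmul)."""
        if self._G is None:
            self._G = self._C.T @ self._C
        return self._G

    def group_tables(self, idx: tuple[int, ...]):
        """(n_gj, d_gj) per-group at-risk/death counts for a cut tuple."""
        cols_n = [self.N[:, i] for i in idx]
        cols_d = [self.D[:, i] for i in idx]
        bounds_n = cols_n + [self.n_t]
        bounds_d = cols_d + [self.d_t]
        n_gj = np.diff(np.stack([np.zeros_like(self.n_t)] + bounds_n), axis=0)
        d_gj = np.diff(np.stack([np.zeros_like(self.d_t)] + bounds_d), axis=0)
        return n_gj, d_gj

    def group_sizes(self, idx) -> np.ndarray:
        bounds = np.concatenate([[0], self.p[list(idx)], [self.n]])
        return np.diff(bounds)

    def group_events(self, idx) -> np.ndarray:
        bounds = np.concatenate([[0.0], self.ev[list(idx)], [self.total_events]])
        return np.diff(bounds)


class BinaryData:
    """Prefix subject/event counts of a binary-outcome cohort sorted by z."""

    def __init__(self, z, y, cut_values):
        z = np.asarray(z, dtype=float)
        y = np.asarray(y, dtype=int)
        order = np.argsort(z, kind="stable")
        self.n = len(z)
        self.z_sorted = z[order]
        yz = y[order]
        self.cut_values = np.asarray(cut_values, dtype=float)
        self.p = np.searchsorted(self.z_sorted, self.cut_values, side="left")
        ecum = np.concatenate([[0], np.cumsum(yz)])
        self.e = ecum[self.p].astype(float)
        self.total_events = float(ecum[-1])

    @property
    def m(self) -> int:
        return len(self.cut_values)


# ---------------------------------------------------------------------------
# grouped Cox partial likelihood (Efron ties)


def _efron_loglik_parts(eta, n_gj, d_gj, jj, frac):
    w = np.exp(eta)
    A = w @ n_gj  # (d,) risk-set weight sum per event time
    a = w @ d_gj  # tie-set weight sum
    denom = A[jj] - frac * a[jj]
    ll = float((d_gj.sum(axis=1) * eta).sum() - np.log(denom).sum())
    return w, denom, ll


def cox_grouped_fit(n_gj, d_gj, jj, frac, tol: float = 1e-9, max_iter: int = 60):
    """Newton fit of the Cox model on a G-level grouped covariate.

    ``n_gj``/``d_gj`` are (G, d) at-risk and death counts per distinct event
    time.  Group 0 is the reference; returns (eta, loglik, loglik_null,
    converged) where ``eta`` are the G-1 free log-hazard levels.
    """
    G = n_gj.shape[0]
    eta = np.zeros(G)
    _, _, ll0 = _efron_loglik_parts(eta, n_gj, d_gj, jj, frac)
    ll = ll0
    converged = False
    for _ in range(max_iter):
        w, denom, ll = _efron_loglik_parts(eta, n_gj, d_gj, jj, frac)
        # B[g, r] = d(denom_r)/d(eta_g), free groups g = 1..G-1
        B = (
            n_gj[1:, jj] * w[1:, None]
            - frac[None, :] * d_gj[1:, jj] * w[1:, None]
        )
        inv = 1.0 / denom
        grad = d_gj[1:].sum(axis=1) - B @ inv
        # observed information: diag(sum B/denom) - sum B_g B_h / denom^2
        info = np.diag(B @ inv) - (B * (inv**2)) @ B.T
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step halving if the likelihood does not improve
        scale = 1.0
        for _ in range(30):
            eta_new = eta.copy()
            eta_new[1:] += scale * step
            _, _, ll_new = _efron_loglik_parts(eta_new, n_gj, d_gj, jj, frac)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        eta = eta_new
        ll = ll_new
    if np.max(np.abs(eta)) > 15:
        converged = False
    return eta[1:], ll, ll0, converged


def null_partial_loglik(time, event) -> float:
    """Efron log partial likelihood of the covariate-free Cox model."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ts = np.unique(time[event == 1])
    n_t = (time[None, :] >= ts[:, None]).sum(axis=1).astype(float)
    d_t = ((time[None, :] == ts[:, None]) & (event[None, :] == 1)).sum(axis=1)
    ll = 0.0
    for n_j, d_j in zip(n_t, d_t.astype(int)):
        fr = np.arange(d_j) / d_j
        ll -= np.log(n_j - fr * d_j).sum()
    return float(ll)


def cox_score_statistic(group, time, event) -> float:
    """Cox score test statistic at beta=0 for an ordinal grouped covariate."""
    sd = SurvivalData(np.asarray(group, dtype=float), time, event, [])
    # rebuild group tables directly from the ordinal labels
    group = np.asarray(group)
    labels = np.unique(group)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ts = sd.ts
    n_gj = np.stack(
        [
            ((time[None, :] >= ts[:, None]) & (group[None, :] == g)).sum(axis=1)
            for g in labels
        ]
    ).astype(float)
    d_gj = np.stack(
        [
            (
                (time[None, :] == ts[:, None])
                & (event[None, :] == 1)
                & (group[None, :] == g)
            ).sum(axis=1)
            for g in labels
        ]
    ).astype(float)
    eta = np.zeros(len(labels))
    w, denom, _ = _efron_loglik_parts(eta, n_gj, d_gj, sd.jj, sd.frac)
    B = (
        n_gj[1:, sd.jj] * w[1:, None]
        - sd.frac[None, :] * d_gj[1:, sd.jj] * w[1:, None]
    )
    inv = 1.0 / denom
    grad = d_gj[1:].sum(axis=1) - B @ inv
    info = np.diag(B @ inv) - (B * (inv**2)) @ B.T
    return float(grad @ np.linalg.solve(info, grad))


# ---------------------------------------------------------------------------
# survival-mode scans


def _feasible_survival(sd: SurvivalData, idx_list, min_size, min_events):
    sizes = np.stack([sd.group_sizes(idx) for idx in idx_list])
    events = np.stack([sd.group_events(idx) for idx in idx_list])
    return (sizes >= min_size).all(axis=1) & (events >= min_events).all(axis=1)


def _logrank_k1(sd: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    O = sd.ev
    E = sd.E_lin
    V = sd.S_lin - np.diag(sd.G)
    ok = V > _SINGULAR_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(ok, (O - E) ** 2 / V, np.nan)
    return stat, ok


def _logrank_k2(sd: SurvivalData, ii, jj_) -> tuple[np.ndarray, np.ndarray]:
    G = sd.G
    Gii, Gjj, Gij = G[ii, ii], G[jj_, jj_], G[ii, jj_]
    u0 = sd.ev[ii] - sd.E_lin[ii]
    u1 = (sd.ev[jj_] - sd.ev[ii]) - (sd.E_lin[jj_] - sd.E_lin[ii])
    V00 = sd.S_lin[ii] - Gii
    V01 = -(Gij - Gii)
    V11 = (sd.S_lin[jj_] - sd.S_lin[ii]) - (Gjj - 2 * Gij + Gii)
    det = V00 * V11 - V01**2
    ok = det > _SINGULAR_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(
            ok, (V11 * u0**2 - 2 * V01 * u0 * u1 + V00 * u1**2) / det, np.nan
        )
    return stat, ok


def scan_survival(
    z,
    time,
    event,
    cut_values,
    k: int,
    criterion: str,
    min_group_size: int,
    min_events_per_group: int,
) -> ScanOutput:
    """Evaluate a survival criterion over all k-tuples of candidate cuts."""
    sd = SurvivalData(z, time, event, cut_values)
    m = sd.m
    if k == 1:
        idx = np.arange(m)[:, None]
    elif k == 2:
        ii, jj_ = np.triu_indices(m, 1)
        idx = np.column_stack([ii, jj_])
    else:
        idx = np.array(list(_increasing_tuples(m, k)), dtype=int).reshape(-1, k)
    idx_list = [tuple(row) for row in idx]
    feas = _feasible_survival(sd, idx_list, min_group_size, min_events_per_group)

    if criterion == "logrank":
        if k == 1:
            stat, ok = _logrank_k1(sd)
        elif k == 2:
            stat, ok = _logrank_k2(sd, idx[:, 0], idx[:, 1])
        else:
            stat, ok = _logrank_general(sd, idx_list)
        valid = feas & ok
        values = np.where(valid, stat, np.nan)
        return ScanOutput(idx, values, valid, df=k)

    if criterion == "cox_lrt":
        values = np.full(len(idx), np.nan)
        valid = feas.copy()
        for r, tup in enumerate(idx_list):
            if not feas[r]:
                continue
            n_gj, d_gj = sd.group_tables(tup)
            _, ll, ll0, conv = cox_grouped_fit(n_gj, d_gj, sd.jj, sd.frac)
            if not conv:
                valid[r] = False
                continue
            values[r] = max(2.0 * (ll - ll0), 0.0)
        return ScanOutput(idx, values, valid, df=k)

    raise ValueError(f"unknown survival criterion {criterion!r}")


def _logrank_general(sd: SurvivalData, idx_list):
    """Per-tuple K-sample log-rank, used only for k > 2."""
    stats_, oks = [], []
    for tup in idx_list:
        n_gj, d_gj = sd.group_tables(tup)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_at_risk = np.where(sd.n_t > 0, n_gj / sd.n_t, 0.0)
        O = d_gj.sum(axis=1)
        E = (frac_at_risk * sd.d_t).sum(axis=1)
        u = (O - E)[:-1]
        V = np.zeros((len(tup), len(tup)))
        for a in range(len(tup)):
            for b in range(len(tup)):
                V[a, b] = (
                    sd.c_t
                    * (
                        (a == b) * frac_at_risk[a]
                        - frac_at_risk[a] * frac_at_risk[b]
                    )
                ).sum()
        try:
            stats_.append(float(u @ np.linalg.solve(V, u)))
            oks.append(True)
        except np.linalg.LinAlgError:
            stats_.append(np.nan)
            oks.append(False)
    return np.array(stats_), np.array(oks)


def _increasing_tuples(m, k):
    import itertools

    return itertools.combinations(range(m), k)


# ---------------------------------------------------------------------------
# binary-mode scans


def _group_counts_binary(bd: BinaryData, idx: np.ndarray):
    """(n_tuples, G) per-group sizes and event counts from prefix arrays."""
    k = idx.shape[1]
    p = bd.p[idx]  # (n_tuples, k)
    e = bd.e[idx]
    sizes = np.diff(
        np.concatenate(
            [np.zeros((len(idx), 1)), p, np.full((len(idx), 1), bd.n)], axis=1
        ),
        axis=1,
    )
    events = np.diff(
        np.concatenate(
            [np.zeros((len(idx), 1)), e, np.full((len(idx), 1), bd.total_events)],
            axis=1,
        ),
        axis=1,
    )
    return sizes, events


def grouped_auc(sizes: np.ndarray, events: np.ndarray) -> np.ndarray:
    """AUC of the saturated grouped score (fitted prob = event fraction).

    Vectorized over the leading axis; ties (within group or between groups
    with identical event fractions) count one half.  Fraction equality is
    decided by exact integer cross-multiplication.
    """
    sizes = np.asarray(sizes, dtype=float)
    events = np.asarray(events, dtype=float)
    G = sizes.shape[-1]
    nonev = sizes - events
    wins = np.zeros(sizes.shape[:-1])
    ties = np.zeros(sizes.shape[:-1])
    for g in range(G):
        for h in range(G):
            if g == h:
                ties = ties + events[..., g] * nonev[..., g]
                continue
            lhs = events[..., g] * sizes[..., h]
            rhs = events[..., h] * sizes[..., g]
            pairs = events[..., g] * nonev[..., h]
            wins = wins + np.where(lhs > rhs, pairs, 0.0)
            ties = ties + np.where(lhs == rhs, pairs, 0.0)
    P = events.sum(axis=-1)
    Nn = nonev.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (wins + 0.5 * ties) / (P * Nn)


def _saturated_loglik(sizes, events):
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(sizes > 0, events / sizes, 0.0)
    return (xlogy(events, p) + xlogy(sizes - events, 1 - p)).sum(axis=-1)


def scan_binary(
    z, y, cut_values, k: int, criterion: str, min_group_size: int
) -> ScanOutput:
    """Evaluate a binary-outcome criterion over all k-tuples of cuts."""
    bd = BinaryData(z, y, cut_values)
    m = bd.m
    if k == 1:
        idx = np.arange(m)[:, None]
    elif k == 2:
        ii, jj_ = np.triu_indices(m, 1)
        idx = np.column_stack([ii, jj_])
    else:
        idx = np.array(list(_increasing_tuples(m, k)), dtype=int).reshape(-1, k)
    sizes, events = _group_counts_binary(bd, idx)
    feas = (sizes >= min_group_size).all(axis=1)

    if criterion == "logistic_lrt":
        # unadjusted model is saturated in groups: closed-form MLE
        n, E = float(bd.n), bd.total_events
        p0 = E / n
        ll_null = float(xlogy(E, p0) + xlogy(n - E, 1 - p0))
        sep = ((events == 0) | (events == sizes)).any(axis=1)
        valid = feas & ~sep
        stat = 2.0 * (_saturated_loglik(sizes, events) - ll_null)
        values = np.where(valid, np.maximum(stat, 0.0), np.nan)
        return ScanOutput(idx, values, valid, df=k)

    if criterion == "max_auc":
        valid = feas.copy()
        auc = grouped_auc(sizes, events)
        values = np.where(valid, auc, np.nan)
        return ScanOutput(idx, values, valid, df=0)

    if criterion == "chi2":
        n, E = float(bd.n), bd.total_events
        exp_e = sizes * (E / n)
        exp_ne = sizes * ((n - E) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = ((events - exp_e) ** 2 / exp_e).sum(axis=1) + (
                ((sizes - events) - exp_ne) ** 2 / exp_ne
            ).sum(axis=1)
        valid = feas & (E > 0) & (E < n)
        values = np.where(valid, stat, np.nan)
        return ScanOutput(idx, values, valid, df=k)

    raise ValueError(f"unknown binary criterion {criterion!r}")
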