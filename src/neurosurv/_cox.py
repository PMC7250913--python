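"""Stratified Cox partial-likelihood engine with late entry.

Numerics live here; the user-facing model assembly is in ``survival``.

Supports Breslow (default) and Efron handling of tied event times,
stratification (separate baseline hazards, pooled coefficients), and
delayed entry (left truncation): a subject is at risk at event time t in
its stratum iff ``entry < t <= time``.  Newton--Raphson with step-halving
maximises the log partial likelihood to a gradient norm of 1e-8.

Score residuals (for cluster-robust sandwich variance) and Schoenfeld
residuals (for proportional-hazards diagnostics) use Breslow risk-set
weighting; with untied data the two ties conventions coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CoxEngineResult",
    "newton_fit",
    "log_partial_likelihood",
    "score_residuals",
    "schoenfeld_residuals",
    "ph_test_statistics",
]


@dataclass
class CoxEngineResult:
    beta: np.ndarray
    loglik: float
    gradient: np.ndarray
    information: np.ndarray       # observed information (-Hessian) at beta
    converged: bool
    n_iter: int
    message: str


def _stratum_indices(strata: np.ndarray | None, n: int) -> list[np.ndarray]:
    if strata is None:
        return [np.arange(n)]
    strata = np.asarray(strata)
    return [np.flatnonzero(strata == s) for s in np.unique(strata)]


def _suffix_sums(values: np.ndarray, keys: np.ndarray, query: np.ndarray) -> np.ndarray:
    """sum of values[i] over keys[i] >= t for each t in query.

    ``values`` may be (n,), (n, p) or (n, p, p).
    """
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    v = values[order]
    suff = np.flip(np.cumsum(np.flip(v, axis=0), axis=0), axis=0)
    pos = np.searchsorted(sorted_keys, query, side="left")
    out_shape = (len(query),) + v.shape[1:]
    out = np.zeros(out_shape)
    inside = pos < len(sorted_keys)
    out[inside] = suff[pos[inside]]
    return out


def _risk_sums(w, X, time, entry, te):
    """S0, S1, S2 over risk sets {entry < t <= time} at each event time te."""
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    S0 = _suffix_sums(w, time, te)
    S1 = _suffix_sums(wx, time, te)
    S2 = _suffix_sums(wxx, time, te)
    if entry is not None:
        S0 = S0 - _suffix_sums(w, entry, te)
        S1 = S1 - _suffix_sums(wx, entry, te)
        S2 = S2 - _suffix_sums(wxx, entry, te)
    return S0, S1, S2


def _event_groups(time, event):
    """Unique event times with counts and indices of the tied events."""
    et = time[event]
    te, first, counts = np.unique(et, return_index=True, return_counts=True)
    return te, counts


def _loglik_terms(beta, X, time, event, entry, strata_idx, ties):
    """Log partial likelihood, gradient and observed information."""
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for idx in strata_idx:
        ev = event[idx]
        if not ev.any():
            continue
        Xs = X[idx]
        ts = time[idx]
        es = entry[idx] if entry is not None else None
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        te, d = _event_groups(ts, ev)
        S0, S1, S2 = _risk_sums(w, Xs, ts, es, te)
        # per-unique-time sums over tied events
        ev_idx = np.flatnonzero(ev)
        order = ev_idx[np.argsort(ts[ev_idx], kind="stable")]
        bounds = np.concatenate([[0], np.cumsum(d)])
        x_ev = Xs[order]
        eta_ev = eta[order]
        dx = np.add.reduceat(x_ev, bounds[:-1], axis=0)
        ll += float(eta_ev.sum()) - shift * d.sum()
        if ties == "breslow":
            ll -= float(d @ np.log(S0))
            xbar = S1 / S0[:, None]
            grad += dx.sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
            v = S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
            info += (d[:, None, None] * v).sum(axis=0)
        elif ties == "efron":
            w_ev = w[order]
            wx_ev = w_ev[:, None] * x_ev
            wxx_ev = wx_ev[:, :, None] * x_ev[:, None, :]
            for k in range(len(te)):
                dk = int(d[k])
                sl = slice(bounds[k], bounds[k + 1])
                tw = w_ev[sl].sum()
                twx = wx_ev[sl].sum(axis=0)
                twxx = wxx_ev[sl].sum(axis=0)
                phi = np.arange(dk) / dk
                s0 = S0[k] - phi * tw
                s1 = S1[k][None, :] - phi[:, None] * twx
                s2 = S2[k][None, :, :] - phi[:, None, None] * twxx
                ll -= float(np.log(s0).sum())
                xb = s1 / s0[:, None]
                grad += dx[k] - xb.sum(axis=0)
                v = s2 / s0[:, None, None] - xb[:, :, None] * xb[:, None, :]
                info += v.sum(axis=0)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return ll, grad, info


def log_partial_likelihood(beta, X, time, event, entry=None, strata=None,
                           ties="breslow"):
    """Value of the (stratified) log partial likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    strata_idx = _stratum_indices(strata, len(X))
    ll, _, _ = _loglik_terms(beta, X, np.asarray(time, float),
                             np.asarray(event, bool),
                             None if entry is None else np.asarray(entry, float),
                             strata_idx, ties)
    return ll


def newton_fit(X, time, event, entry=None, strata=None, ties="breslow",
               tol=1e-8, max_iter=100) -> CoxEngineResult:
    """Maximise the stratified log partial likelihood by Newton--Raphson
    with step-halving; converged when the gradient 2-norm <= tol."""
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = None if entry is None else np.asarray(entry, dtype=float)
    n, p = X.shape
    strata_idx = _stratum_indices(strata, n)
    if not event.any():
        raise ValueError("no events in the data")
    center = X.mean(axis=0)
    Xc = X - center  # centering leaves beta unchanged, improves conditioning

    beta = np.zeros(p)
    ll, grad, info = _loglik_terms(beta, Xc, time, event, entry, strata_idx, ties)
    message = "converged"
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) <= tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix (constant covariate in the event set?)"
            break
        new_beta = beta + step
        new_ll, new_grad, new_info = _loglik_terms(new_beta, Xc, time, event,
                                                   entry, strata_idx, ties)
        halves = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halves < 40:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _loglik_terms(new_beta, Xc, time, event,
                                                       entry, strata_idx, ties)
            halves += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(beta).max() > 25:
            message = ("coefficient diverging (|beta| > 25): monotone partial "
                       "likelihood / perfect separation suspected")
            break
    else:
        message = f"no convergence in {max_iter} iterations"
    if converged and np.abs(beta).max() > 15:
        # gradient can vanish on a monotone likelihood plateau
        converged = False
        message = ("coefficient implausibly large (|beta| > 15): monotone "
                   "partial likelihood / perfect separation suspected")
    elif converged:
        message = "converged"
    return CoxEngineResult(beta=beta, loglik=ll, gradient=grad, information=info,
                           converged=converged, n_iter=it, message=message)


def _event_time_tables(w, X, time, event, entry, te):
    S0, S1, _ = _risk_sums(w, X, time, entry, te)
    return S0, S1


def score_residuals(X, time, event, beta, entry=None, strata=None):
    """Per-record score residuals at ``beta`` (Breslow weighting).

    Rows sum to the score vector; aggregating within clusters and forming
    ``I^-1 (sum_g u_g u_g') I^-1`` gives the sandwich variance.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = None if entry is None else np.asarray(entry, dtype=float)
    n, p = X.shape
    center = X.mean(axis=0)
    Xc = X - center
    out = np.zeros((n, p))
    for idx in _stratum_indices(strata, n):
        ev = event[idx]
        if not ev.any():
            continue
        Xs = Xc[idx]
        ts = time[idx]
        es = entry[idx] if entry is not None else None
        eta = Xs @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        te, d = _event_groups(ts, ev)
        S0, S1 = _event_time_tables(w, Xs, ts, ev, es, te)
        xbar = S1 / S0[:, None]
        cum0 = np.concatenate([[0.0], np.cumsum(d / S0)])
        cum1 = np.concatenate([np.zeros((1, p)),
                               np.cumsum(d[:, None] * S1 / S0[:, None] ** 2, axis=0)])
        hi = np.searchsorted(te, ts, side="right")
        lo = (np.searchsorted(te, es, side="right") if es is not None
              else np.zeros(len(ts), dtype=int))
        a = cum0[hi] - cum0[lo]
        b = cum1[hi] - cum1[lo]
        res = -w[:, None] * (Xs * a[:, None] - b)
        ev_pos = np.flatnonzero(ev)
        k_of = np.searchsorted(te, ts[ev_pos])
        res[ev_pos] += Xs[ev_pos] - xbar[k_of]
        out[idx] = res
    return out


def schoenfeld_residuals(X, time, event, beta, entry=None, strata=None):
    """Schoenfeld residuals x_i - xbar(t_i) for each event, with their times.

    Returns (event_times, residual matrix) sorted by time (ties kept as
    separate rows, stratum risk sets respected).
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    entry = None if entry is None else np.asarray(entry, dtype=float)
    n, p = X.shape
    center = X.mean(axis=0)
    Xc = X - center
    all_t: list[np.ndarray] = []
    all_r: list[np.ndarray] = []
    for idx in _stratum_indices(strata, n):
        ev = event[idx]
        if not ev.any():
            continue
        Xs = Xc[idx]
        ts = time[idx]
        es = entry[idx] if entry is not None else None
        eta = Xs @ beta
        w = np.exp(eta - eta.max())
        te, _ = _event_groups(ts, ev)
        S0, S1 = _event_time_tables(w, Xs, ts, ev, es, te)
        xbar = S1 / S0[:, None]
        ev_pos = np.flatnonzero(ev)
        k_of = np.searchsorted(te, ts[ev_pos])
        all_t.append(ts[ev_pos])
        all_r.append(Xs[ev_pos] - xbar[k_of])
    t = np.concatenate(all_t)
    r = np.concatenate(all_r)
    order = np.argsort(t, kind="stable")
    return t[order], r[order]


def ph_test_statistics(event_times, schoenfeld, information, transform="identity",
                       km_times=None, km_survival=None):
    """Grambsch–Therneau score test for a time trend in Schoenfeld residuals.

    Per-covariate chi-square(1) statistics and a global chi-square(p),
    using the average-information approximation V(t_k) ~ I / d.
    ``transform`` maps event time to the trend variable g(t): "identity"
    or "km" (1 - Kaplan-Meier survival just before t, supplied via
    km_times/km_survival as a right-continuous step function).
    """
    s = np.asarray(schoenfeld, dtype=float)
    t = np.asarray(event_times, dtype=float)
    d, p = s.shape
    if d < 2:
        raise ValueError("PH test undefined with fewer than 2 events")
    if transform == "identity":
        g = t.copy()
    elif transform == "km":
        if km_times is None or km_survival is None:
            raise ValueError("km transform requires km_times and km_survival")
        # right-continuous KM evaluated at t (the cox.zph / lifelines convention)
        pos = np.searchsorted(km_times, t, side="right") - 1
        surv_at = np.where(pos >= 0, np.asarray(km_survival)[np.clip(pos, 0, None)], 1.0)
        g = 1.0 - surv_at
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    gg = float(gc @ gc)
    if gg <= 0:
        raise ValueError("degenerate time transform (all event times equal)")
    u = s.T @ gc                       # (p,)
    inv_info = np.linalg.inv(information)
    chi_global = float(d * u @ inv_info @ u / gg)
    p_global = float(stats.chi2.sf(chi_global, p))
    w = inv_info @ u
    chi_each = d * w**2 / (np.diag(inv_info) * gg)
    p_each = stats.chi2.sf(chi_each, 1)
    return chi_each, p_each, chi_global, p_global
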