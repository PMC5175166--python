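"""Linking TF activity to patient outcome.

Per-TF screening dichotomizes the cohort at the median activity (ties to
the low group) and compares the two Kaplan-Meier curves with the
two-sample log-rank statistic.  Only TFs with at least ``min_events``
deaths in the cohort are tested, and BH adjustment runs across the
tested TFs only.  The multivariate layer fits Cox proportional-hazards
models on the continuous activity values (plus tumour purity when
available) and selects variables by bidirectional stepwise search on
AIC = -2 log partial likelihood + 2k, starting from the empty model.
Ties in event times are handled with the Breslow approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import bh_adjust
from .io import ClinicalTable
from .personalized import SampleActivityMatrix

__all__ = ["SurvivalResult", "CoxModelResult", "km_logrank", "logrank_screen",
           "cox_fit", "cox_stepwise", "km_curve"]

_MIN_EVENTS_DEFAULT = 10


@dataclass
class SurvivalResult:
    tf_name: str
    n_high: int
    n_low: int
    n_events: int
    logrank_stat: float
    p: float
    adj_p: float = math.nan
    worse_group: str = ""

    @property
    def tested(self) -> bool:
        return not math.isnan(self.p)


@dataclass
class CoxModelResult:
    """Outcome of the stepwise-AIC Cox selection.

    ``trace`` records the ordered add/drop moves as
    (action, variable, AIC after the move).
    """

    selected_variables: list[str]
    coefficients: pd.DataFrame
    aic: float
    null_aic: float
    trace: list[tuple[str, str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# log-rank


def _logrank_two_sample(time: np.ndarray, event: np.ndarray,
                        in_high: np.ndarray) -> tuple[float, float]:
    """Two-sample log-rank chi-square: (sum(O-E))^2 / sum(V) over the
    distinct event times, with the hypergeometric variance."""
    order = np.argsort(time, kind="stable")
    time, event, in_high = time[order], event[order], in_high[order]
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in_high).sum()
        dead = (time == t) & (event == 1)
        d = dead.sum()
        d1 = (dead & in_high).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    from scipy import stats as sps

    stat = o_minus_e**2 / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


def km_logrank(activity: pd.Series, clinical: ClinicalTable, tf_name: str = "",
               min_events: int = _MIN_EVENTS_DEFAULT,
               split_quantile: float = 0.5) -> SurvivalResult:
    """Median-split log-rank test of one TF's activity against survival.

    Samples at or below the split value go to the low-activity group.
    The result is flagged untested when the cohort has fewer than
    ``min_events`` deaths or when the activity carries no split (all
    values identical, or every value tied at the split).
    """
    cl = clinical.data.set_index("sample_id")
    common = [s for s in cl.index if s in activity.index and not math.isnan(activity[s])]
    if not common:
        raise ValueError("no samples shared between activity and clinical table")
    act = activity.loc[common].to_numpy(dtype=float)
    time = cl.loc[common, "time"].to_numpy(dtype=float)
    event = cl.loc[common, "event"].to_numpy(dtype=int)
    n_events = int(event.sum())
    if n_events < min_events:
        return SurvivalResult(tf_name, 0, 0, n_events, math.nan, math.nan)
    cut = float(np.quantile(act, split_quantile))
    in_high = act > cut
    n_high, n_low = int(in_high.sum()), int((~in_high).sum())
    if n_high == 0 or n_low == 0:
        return SurvivalResult(tf_name, n_high, n_low, n_events, math.nan, math.nan)
    stat, p = _logrank_two_sample(time, event, in_high)
    # which group fares worse: compare observed vs expected deaths in high
    worse = ""
    if stat > 0:
        d_high = event[in_high].sum()
        e_high = _expected_deaths_high(time, event, in_high)
        worse = "high" if d_high > e_high else "low"
    return SurvivalResult(tf_name, n_high, n_low, n_events, stat, p,
                          worse_group=worse)


def _expected_deaths_high(time, event, in_high) -> float:
    e = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = ((time == t) & (event == 1)).sum()
        e += d * (at_risk & in_high).sum() / at_risk.sum()
    return e


def logrank_screen(activities: SampleActivityMatrix, clinical: ClinicalTable,
                   min_events: int = _MIN_EVENTS_DEFAULT,
                   split_quantile: float = 0.5) -> list[SurvivalResult]:
    """Log-rank screen across all TFs; BH over the tested TFs only."""
    results = [km_logrank(activities.activity.loc[tf].dropna(), clinical,
                          tf_name=tf, min_events=min_events,
                          split_quantile=split_quantile)
               for tf in activities.tf_names]
    tested = [r for r in results if r.tested]
    if tested:
        adj = bh_adjust([r.p for r in tested])
        for r, a in zip(tested, adj):
            r.adj_p = float(a)
    results.sort(key=lambda r: (math.isnan(r.adj_p), r.adj_p, r.tf_name))
    return results


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier survival estimate (time, at-risk, deaths, survival)."""
    order = np.argsort(time, kind="stable")
    time, event = np.asarray(time)[order], np.asarray(event)[order]
    rows = []
    surv = 1.0
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        surv *= 1 - d / n
        rows.append((t, int(n), int(d), surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "survival"])


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties) and stepwise AIC


def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                event: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood with gradient and Hessian.

    Samples must be sorted by increasing time; risk sets are suffix
    sums, accumulated per distinct event time.
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    w = np.exp(eta - eta.max())
    log_shift = eta.max()
    # suffix cumulative sums over the risk set
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1] if p else None
    s2 = (np.cumsum((w[:, None, None] * X[:, :, None] * X[:, None, :])[::-1],
                    axis=0)[::-1] if p else None)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        # deaths in the tie block [i, j)
        dead = np.nonzero(event[i:j] == 1)[0] + i
        d = dead.size
        if d:
            risk0 = s0[i]
            ll += eta[dead].sum() - d * (math.log(risk0) + log_shift)
            if p:
                r1 = s1[i] / risk0
                grad += X[dead].sum(axis=0) - d * r1
                hess -= d * (s2[i] / risk0 - np.outer(r1, r1))
        i = j
    return ll, grad, hess


def cox_fit(X: pd.DataFrame, time: np.ndarray, event: np.ndarray,
            max_iter: int = 50, tol: float = 1e-9) -> tuple[pd.DataFrame, float]:
    """Newton-Raphson Cox fit; returns a coefficient table (coef, se,
    Wald p per variable) and the maximized partial log-likelihood."""
    from scipy import stats as sps

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    Xs = X.to_numpy(dtype=float)[order] if X.shape[1] else np.empty((len(time), 0))
    ts, es = time[order], event[order]
    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, Xs, ts, es)
    for _ in range(max_iter):
        if p == 0:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise ValueError("singular information matrix in Cox fit")
        # halve the step until the likelihood does not decrease
        for _ in range(20):
            new = beta + step
            ll_new, grad_new, hess_new = _cox_loglik(new, Xs, ts, es)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        if abs(ll_new - ll) < tol:
            beta, ll, grad, hess = new, ll_new, grad_new, hess_new
            break
        beta, ll, grad, hess = new, ll_new, grad_new, hess_new
    if p:
        se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        wald_p = sps.chi2.sf((beta / se) ** 2, df=1)
    else:
        se = np.zeros(0)
        wald_p = np.zeros(0)
    coefs = pd.DataFrame({"coef": beta, "se": se, "p": wald_p},
                         index=list(X.columns))
    return coefs, float(ll)


def _aic(ll: float, k: int) -> float:
    return -2.0 * ll + 2.0 * k


def cox_stepwise(activities: SampleActivityMatrix | pd.DataFrame,
                 clinical: ClinicalTable, include_purity: bool = False,
                 candidates: list[str] | None = None) -> CoxModelResult:
    """Bidirectional stepwise-AIC selection of a multivariate Cox model.

    Candidate variables are the continuous per-sample TF activities (and
    ``PURITY`` when present and requested).  Starting from the empty
    model, each step applies the single variable addition or removal
    that most decreases AIC, stopping when no move improves it; ties
    between moves break by variable name.  Constant candidates and
    candidates perfectly collinear (|r| = 1) with an already-included
    variable are dropped and logged.
    """
    if isinstance(activities, SampleActivityMatrix):
        act = activities.activity
    else:
        act = activities
    cl = clinical.data.set_index("sample_id")
    samples = [s for s in act.columns if s in cl.index]
    if not samples:
        raise ValueError("no samples shared between activities and clinical table")
    design = act[samples].T.copy()
    design.columns = [str(c) for c in design.columns]
    if include_purity:
        if not clinical.has_purity:
            raise ValueError("include_purity requested but no purity column present")
        design["PURITY"] = cl.loc[samples, "purity"].to_numpy(dtype=float)
    time = cl.loc[samples, "time"].to_numpy(dtype=float)
    event = cl.loc[samples, "event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the cohort")

    pool = sorted(candidates) if candidates is not None else sorted(design.columns)
    warnings_: list[str] = []
    # drop candidates with missing values or zero variance
    usable = []
    for v in pool:
        col = design[v].to_numpy(dtype=float)
        if np.isnan(col).any():
            warnings_.append(f"{v}: missing values, dropped from candidates")
        elif np.ptp(col) == 0:
            warnings_.append(f"{v}: constant, dropped from candidates")
        else:
            usable.append(v)
    if event.sum() < 2 * len(usable):
        warnings_.append(
            f"only {int(event.sum())} events for {len(usable)} candidates; "
            "selection may be unstable")

    def model_aic(variables: list[str]) -> float:
        _, ll = cox_fit(design[variables], time, event)
        return _aic(ll, len(variables))

    current: list[str] = []
    current_aic = model_aic(current)
    null_aic = current_aic
    trace: list[tuple[str, str, float]] = []
    while True:
        moves: list[tuple[float, str, str]] = []
        for v in usable:
            if v in current:
                continue
            col = design[v].to_numpy(dtype=float)
            collinear = False
            for u in current:
                r = np.corrcoef(col, design[u].to_numpy(dtype=float))[0, 1]
                if abs(r) >= 1 - 1e-12:
                    collinear = True
                    msg = f"{v}: |r|=1 with included {u}, skipped"
                    if msg not in warnings_:
                        warnings_.append(msg)
                    break
            if collinear:
                continue
            try:
                moves.append((model_aic(current + [v]), "add", v))
            except (ValueError, np.linalg.LinAlgError):
                continue
        for v in current:
            reduced = [u for u in current if u != v]
            moves.append((model_aic(reduced), "drop", v))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        best_aic, action, var = moves[0]
        if best_aic >= current_aic - 1e-10:
            break
        if action == "add":
            current = sorted(current + [var])
        else:
            current = [u for u in current if u != var]
        current_aic = best_aic
        trace.append((action, var, best_aic))
    coefs, ll = cox_fit(design[current], time, event)
    return CoxModelResult(selected_variables=current, coefficients=coefs,
                          aic=_aic(ll, len(current)), null_aic=null_aic,
                          trace=trace, warnings=warnings_)
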