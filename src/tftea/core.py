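"""The TF target enrichment statistic.

A TF's activity change between two conditions is read off the placement
of its target genes in a ranked differential-expression list: membership
(1 = target) is regressed logistically on the normalized reverse rank
x = (N - r + 1)/N, so x is largest at the top of the list.  A positive
slope means targets pile up among the most up-regulated genes (TF
activated in condition A); a negative slope means deactivation.  The
null slope = 0 is tested with the Wald statistic (beta/se)^2 against a
chi-square with one degree of freedom, and Benjamini-Hochberg FDR is
applied across the TFs actually tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import TFTargetCollection
from .ranking import RankedList

__all__ = ["EnrichmentResult", "tftea_test", "run_collection", "bh_adjust"]

_MIN_TARGETS_DEFAULT = 10


@dataclass
class EnrichmentResult:
    """Per-TF enrichment outcome.

    ``slope`` is the logistic coefficient of target membership on the
    normalized reverse rank; ``wald`` is the chi-square(df=1) statistic
    behind ``p`` — (slope/se)^2 for the regular ML fit, or the penalized
    likelihood-ratio statistic when the fit fell back to Firth under
    complete separation (flagged ``separated``).  ``direction`` is +1
    for activation (positive slope), -1 for deactivation.  Untested TFs
    (too few targets in the universe) carry NaN p-values and
    ``converged=False``.
    """

    tf_name: str
    n_targets: int
    slope: float
    se: float
    wald: float
    p: float
    adj_p: float = math.nan
    converged: bool = True
    separated: bool = False

    @property
    def direction(self) -> int:
        if math.isnan(self.slope) or self.slope == 0:
            return 0
        return 1 if self.slope > 0 else -1

    @property
    def tested(self) -> bool:
        return not math.isnan(self.p)


def _untested(tf_name: str, n_targets: int) -> EnrichmentResult:
    nan = math.nan
    return EnrichmentResult(tf_name, n_targets, nan, nan, nan, nan,
                            converged=False)


def _mu_w(X: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return mu, np.clip(mu * (1.0 - mu), 1e-12, None)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -700, 700)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _irls_logistic(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML fit of y ~ intercept + x by iteratively reweighted least
    squares; returns (coefficients, standard errors, converged)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    # start the intercept at the logit of the base rate
    ybar = y.mean()
    if 0 < ybar < 1:
        beta[0] = math.log(ybar / (1 - ybar))
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        mu, w = _mu_w(X, beta)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - mu)
        try:
            beta = beta + np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        ll = _loglik(X, y, beta)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    _, w = _mu_w(X, beta)
    info = X.T @ (X * w[:, None])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return beta, se, converged


def _firth_penalized_ll(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Log-likelihood plus the Jeffreys-prior penalty 0.5 log|I(beta)|."""
    _, w = _mu_w(X, beta)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return _loglik(X, y, beta) + 0.5 * logdet


def _firth_logistic(x: np.ndarray, y: np.ndarray, fix_slope: bool = False,
                    tol: float = 1e-8, max_iter: int = 500
                    ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth-penalized logistic fit (Jeffreys prior), the fallback under
    complete separation where the ML slope diverges.

    With ``fix_slope`` the slope is constrained to 0 and only the
    intercept is profiled, as needed by the penalized likelihood-ratio
    test; the penalty always uses the full-design information.
    """
    X = np.column_stack([np.ones_like(x), x])
    free = np.array([True, not fix_slope])
    beta = np.zeros(2)
    converged = False
    pl_old = _firth_penalized_ll(X, y, beta)
    for _ in range(max_iter):
        mu, w = _mu_w(X, beta)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        # hat-matrix diagonal of the weighted full design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = (X.T @ (y - mu + h * (0.5 - mu)))[free]
        sub_info = info[np.ix_(free, free)]
        try:
            step_free = np.linalg.solve(sub_info, score)
        except np.linalg.LinAlgError:
            break
        step = np.zeros(2)
        step[free] = step_free
        # halve the step until the penalized likelihood does not drop
        for _ in range(25):
            pl_new = _firth_penalized_ll(X, y, beta + step)
            if pl_new >= pl_old - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if abs(pl_new - pl_old) < tol and np.max(np.abs(step)) < 1e-6:
            converged = True
            break
        pl_old = pl_new
    _, w = _mu_w(X, beta)
    info = X.T @ (X * w[:, None])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    return beta, se, converged


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: all targets strictly above (or below) all
    non-targets on the predictor."""
    x1, x0 = x[y == 1], x[y == 0]
    if x1.size == 0 or x0.size == 0:
        return False
    return x1.min() > x0.max() or x1.max() < x0.min()


def tftea_test(ranked: RankedList, targets: set[str], tf_name: str = "",
               min_targets: int = _MIN_TARGETS_DEFAULT,
               predictor: str = "rank") -> EnrichmentResult:
    """Test one TF's target set for asymmetric placement in the ranked list.

    Parameters
    ----------
    ranked : RankedList
        Genes ordered by the differential statistic, descending.
    targets : set of str
        The TF's target gene ids; only those present in the ranked
        universe enter the test.
    min_targets : int
        Minimum overlap with the universe for the test to run
        (default 10); below it the result is flagged untested.
    predictor : {"rank", "statistic"}
        Regress membership on the normalized reverse rank (default) or
        on the raw statistic value.

    Returns
    -------
    EnrichmentResult
        Slope, Wald chi-square (df=1) and its two-sided tail p-value.
    """
    from scipy import stats as sps

    n = ranked.n
    if n == 0:
        raise ValueError("empty ranked list")
    member = np.isin(np.asarray(ranked.gene_ids, dtype=object), list(targets))
    n_overlap = int(member.sum())
    if n_overlap < min_targets or n_overlap >= n:
        return _untested(tf_name, n_overlap)
    if predictor == "rank":
        # midranks for tied statistics: genes the statistic cannot
        # distinguish must not contribute placement signal
        r = sps.rankdata(-ranked.statistic, method="average")
        x = (n - r + 1.0) / n
    elif predictor == "statistic":
        x = ranked.statistic.astype(float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    y = member.astype(float)
    if np.ptp(x) == 0:
        # fully tied list: no asymmetry is observable, slope pinned at 0
        return EnrichmentResult(tf_name, n_overlap, 0.0, math.nan, 0.0, 1.0)

    separated = _is_separated(x, y)
    if not separated:
        beta, se, converged = _irls_logistic(x, y)
        # quasi-separation: the fit saturates (probabilities pinned at
        # 0/1 across the predictor range) and the Wald statistic
        # collapses even though IRLS converged (Hauck-Donner effect)
        if converged and np.all(np.isfinite(beta)) \
                and abs(beta[1]) * np.ptp(x) > 20:
            separated = True
    if separated:
        # Firth fallback: the ML slope diverges and its Wald statistic
        # collapses, so test slope = 0 with the penalized likelihood
        # ratio instead (the logistf convention)
        beta, se, converged = _firth_logistic(x, y)
        beta0, _, conv0 = _firth_logistic(x, y, fix_slope=True)
        if not (converged and conv0):
            res = _untested(tf_name, n_overlap)
            res.separated = True
            return res
        X = np.column_stack([np.ones_like(x), x])
        chi2_stat = 2.0 * (_firth_penalized_ll(X, y, beta)
                           - _firth_penalized_ll(X, y, beta0))
        chi2_stat = max(chi2_stat, 0.0)
    else:
        if not converged or not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
            return _untested(tf_name, n_overlap)
        chi2_stat = (beta[1] / se[1]) ** 2 if se[1] > 0 else math.inf
    slope, slope_se = float(beta[1]), float(se[1])
    p = float(sps.chi2.sf(chi2_stat, df=1))
    return EnrichmentResult(tf_name, n_overlap, slope, slope_se, float(chi2_stat),
                            p, converged=converged, separated=separated)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j>=i}( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_collection(ranked: RankedList, coll: TFTargetCollection,
                   min_targets: int = _MIN_TARGETS_DEFAULT,
                   predictor: str = "rank") -> list[EnrichmentResult]:
    """Run the enrichment test over every TF in a collection.

    BH adjustment is computed over the tested (non-NA) results only;
    results come back sorted by adjusted p then TF name.
    """
    if len(coll) == 0:
        raise ValueError("empty TF collection")
    if ranked.n == 0:
        raise ValueError("empty ranked list")
    results = [tftea_test(ranked, coll[tf], tf_name=tf,
                          min_targets=min_targets, predictor=predictor)
               for tf in coll]
    tested = [r for r in results if r.tested]
    if tested:
        adj = bh_adjust([r.p for r in tested])
        for r, a in zip(tested, adj):
            r.adj_p = float(a)
    results.sort(key=lambda r: (math.isnan(r.adj_p), r.adj_p, r.tf_name))
    return results


def results_frame(results: list[EnrichmentResult]):
    """Tabulate enrichment results (one row per TF)."""
    import pandas as pd

    return pd.DataFrame(
        {"tf": [r.tf_name for r in results],
         "n_targets": [r.n_targets for r in results],
         "slope": [r.slope for r in results],
         "se": [r.se for r in results],
         "wald": [r.wald for r in results],
         "p": [r.p for r in results],
         "adj_p": [r.adj_p for r in results],
         "direction": [r.direction for r in results],
         "converged": [r.converged for r in results],
         "separated": [r.separated for r in results]})
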