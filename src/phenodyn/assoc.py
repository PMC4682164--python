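"""Bivariate association with ARMA errors and automated order selection.

Longitudinal session series are autocorrelated, so the naive Pearson test
of association is anticonservative.  Each pair is therefore tested by
regression with ARMA(p, q) errors:

1. a KPSS stationarity pretest picks the differencing order d in {0, 1};
2. the error order (p, q) is chosen over the exhaustive grid [0..3]^2 by
   corrected AIC, with candidate parameters from fast closed-form
   estimators (Levinson-Durbin for pure AR, Hannan-Rissanen regression for
   MA/mixed terms) and exact Gaussian likelihoods from the innovations
   algorithm;
3. the slope is estimated by generalized least squares after whitening
   with the selected ARMA process, and tested against a t distribution
   with n - k - (p + q) degrees of freedom.

The order is selected on the (differenced, centred) response rather than
on OLS residuals: under the null a spurious OLS slope absorbs part of the
response autocorrelation, which biases residual-based selection toward
under-whitening and inflates the type-I error.

Multiplicity control follows the study's convention: Benjamini-Hochberg
FDR per scan with an additional |r| > 0.2 effect-size gate, plus a
Bonferroni-corrected p-value for headline tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.innovations import arma_innovations
from statsmodels.tsa.stattools import kpss

__all__ = [
    "AssocResult",
    "arima_assoc",
    "scan_pairs",
    "bh_fdr",
    "replication_power",
    "arma_error_regression",
]

MAX_ORDER = 3
MIN_N = 10

VARIABLE_CLASSES = frozenset({
    "behav", "wincorr", "bwcorr", "netdat", "wgcna",
    "metab", "fullmetab", "food", "immport",
})


@dataclass
class AssocResult:
    """One pair's correlation, ARMA-error regression test and bookkeeping."""

    var_a: str
    var_b: str
    r: float
    t: float
    p: float
    order: tuple            # (p, d, q)
    n: int
    class_a: str = ""
    class_b: str = ""
    coef: float = 0.0


# ---------------------------------------------------------------------------
# fast ARMA order selection

def _levinson(acov: np.ndarray, p: int):
    """AR(p) coefficients and innovation variance via Levinson-Durbin."""
    phi = np.zeros(p)
    prev = np.zeros(p)
    v = acov[0]
    for k in range(1, p + 1):
        if v <= 0:
            return None
        acc = acov[k] - (prev[:k - 1] @ acov[1:k][::-1] if k > 1 else 0.0)
        refl = acc / v
        phi[:k - 1] = prev[:k - 1] - refl * prev[:k - 1][::-1]
        phi[k - 1] = refl
        v *= (1.0 - refl ** 2)
        prev[:k] = phi[:k]
    return phi[:p].copy(), v


def _stationary(poly_coefs: np.ndarray) -> bool:
    if poly_coefs.size == 0:
        return True
    return bool(np.all(np.abs(np.roots(poly_coefs)) < 1.0))


def _candidate_params(e: np.ndarray, max_p: int, max_q: int) -> dict:
    """Closed-form ARMA(p, q) candidates for every grid point.

    Pure AR terms come from Levinson-Durbin; terms with q > 0 from the
    Hannan-Rissanen two-stage regression (long-AR innovations, then least
    squares on lagged values and lagged innovations).  Non-stationary or
    non-invertible candidates are dropped.
    """
    n = e.size
    long_ar = min(max(2 * (max_p + max_q), 4), n // 4)
    max_p = min(max_p, long_ar)
    max_q = min(max_q, long_ar)
    acov = np.array([e[:n - k] @ e[k:] for k in range(long_ar + 1)]) / n
    out = {(0, 0): (np.empty(0), np.empty(0), max(float(acov[0]), 1e-12))}
    for p in range(1, max_p + 1):
        r = _levinson(acov, p)
        if r is None:
            continue
        phi, v = r
        if not _stationary(np.r_[1.0, -phi]):
            continue
        out[(p, 0)] = (phi, np.empty(0), max(v, 1e-12))

    rr = _levinson(acov, long_ar)
    if rr is None:
        return out
    phi_l, _ = rr
    ehat = np.zeros(n)
    lagmat = np.column_stack([e[long_ar - k: n - k] for k in range(1, long_ar + 1)])
    ehat[long_ar:] = e[long_ar:] - lagmat @ phi_l
    for p in range(0, max_p + 1):
        for q in range(1, max_q + 1):
            m = max(p, q) + long_ar
            if n - m < p + q + 4:
                continue
            idx = np.arange(m, n)
            cols = ([e[idx - k] for k in range(1, p + 1)]
                    + [ehat[idx - k] for k in range(1, q + 1)])
            Z = np.column_stack(cols)
            try:
                coef, _, _, _ = np.linalg.lstsq(Z, e[idx], rcond=None)
            except np.linalg.LinAlgError:
                continue
            ar, ma = coef[:p], coef[p:]
            # inverse characteristic roots inside the unit circle:
            # stationary AR, invertible MA
            if p and np.any(np.abs(np.roots(np.r_[1.0, -ar])) >= 1):
                continue
            if q and np.any(np.abs(np.roots(np.r_[1.0, ma])) >= 1):
                continue
            resid = e[idx] - Z @ coef
            out[(p, q)] = (ar, ma, max(float(resid @ resid / idx.size), 1e-12))
    return out


def _select_order(e: np.ndarray, max_p: int = MAX_ORDER, max_q: int = MAX_ORDER):
    """AICc-best (p, q) over the exhaustive grid; deterministic tie-breaks."""
    n = e.size
    cand = _candidate_params(e, max_p, max_q)
    best = None
    best_aicc = np.inf
    best_par = None
    failures = []
    for (p, q) in sorted(cand):
        ar, ma, s2 = cand[(p, q)]
        try:
            ll = arma_innovations.arma_loglike(e, ar_params=ar, ma_params=ma,
                                               sigma2=s2)
        except Exception as exc:  # pragma: no cover - degenerate numerics
            failures.append(((p, q), repr(exc)))
            continue
        k = p + q + 1
        if n - k - 1 <= 0:
            continue
        aicc = -2.0 * ll + 2.0 * k * n / (n - k - 1)
        if aicc < best_aicc - 1e-12:
            best_aicc = aicc
            best = (p, q)
            best_par = (ar, ma, s2)
    if best is None:
        raise RuntimeError(f"no ARMA grid point could be fit; failures: {failures}")
    return best, best_par


def _whiten(v: np.ndarray, ar: np.ndarray, ma: np.ndarray, s2: float) -> np.ndarray:
    u, mse = arma_innovations.arma_innovations(
        np.ascontiguousarray(v, dtype=float), ar_params=ar, ma_params=ma,
        sigma2=s2)
    return np.asarray(u) / np.sqrt(np.asarray(mse))


def arma_error_regression(y: np.ndarray, X: np.ndarray, d: int = 0,
                          max_p: int = MAX_ORDER, max_q: int = MAX_ORDER,
                          select_on: str = "response", refine: bool = True):
    """GLS regression of y on X with automatically selected ARMA errors.

    Returns ``(beta, tvals, pvals, order)`` with ``order = (p, d, q)``.
    ``X`` must include the intercept column.  With d = 1 both sides are
    differenced first.  ``select_on`` picks the series the error order is
    chosen on: "response" (default; right for stochastic regressors, where
    residual-based selection under-whitens) or "residual" (right for
    deterministic regressors such as trends and state contrasts, whose
    effect would otherwise be absorbed into the error model).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if d == 1:
        y = np.diff(y)
        X = np.diff(X, axis=0)
        X[:, 0] = 1.0  # differenced intercept column becomes a drift term
    n = y.size
    if select_on == "residual":
        b0, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sel_series = y - X @ b0
    else:
        sel_series = y - y.mean()
    (p, q), (ar, ma, s2) = _select_order(sel_series, max_p, max_q)
    k = X.shape[1]
    df = n - k - (p + q)
    if df <= 0:
        raise RuntimeError("not enough observations for the selected order")

    def gls(ar_, ma_, s2_):
        if p == 0 and q == 0:
            Xw_, yw_ = X, y
        else:
            yw_ = _whiten(y, ar_, ma_, s2_)
            Xw_ = np.column_stack([_whiten(X[:, j], ar_, ma_, s2_)
                                   for j in range(X.shape[1])])
        b, _, _, _ = np.linalg.lstsq(Xw_, yw_, rcond=None)
        return b, Xw_, yw_

    beta, Xw, yw = gls(ar, ma, s2)
    # inference from this selection-consistent fit: its null t statistics
    # are t-distributed to the far tail, which BH-FDR at scan scale relies on
    resid = yw - Xw @ beta
    s2_hat = float(resid @ resid) / df
    cov = s2_hat * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals[se == 0] = 1.0

    if refine and p + q > 0 and select_on == "response":
        # point estimate only: iterate a parameter refresh at the selected
        # order.  Parameters fitted to the raw response absorb part of a
        # true slope and attenuate the estimate, so they are re-estimated
        # on the residuals around the current whitened fit until the slope
        # stabilizes.  The refreshed fit adapts to the data and its t
        # statistic is no longer calibrated, so t and p above are kept
        # from the unrefined fit.
        for _ in range(4):
            prev = beta.copy()
            refreshed = _candidate_params(y - X @ beta, p, q).get((p, q))
            if refreshed is None:
                break
            ar2, ma2, s22 = refreshed
            beta, _, _ = gls(ar2, ma2, s22)
            if np.max(np.abs(beta - prev)) < 1e-6:
                break
    return beta, tvals, pvals, (p, d, q)


def _kpss_d(y: np.ndarray) -> int:
    """Differencing order in {0, 1} from a KPSS level-stationarity pretest."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            _, pval, _, _ = kpss(y, regression="c", nlags="auto")
        except Exception:
            return 0
    return 1 if pval < 0.05 else 0


def arima_assoc(x, y, min_n: int = MIN_N, max_p: int = MAX_ORDER,
                max_q: int = MAX_ORDER, var_a: str = "x", var_b: str = "y",
                class_a: str = "", class_b: str = "") -> AssocResult:
    """Test association between two session series with ARMA errors.

    Missing values are removed pairwise (the series are compacted over the
    jointly observed sessions).  ``r`` is the plain Pearson correlation of
    the pair; ``t`` and ``p`` come from the ARMA-error regression of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must share the session index")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < min_n:
        raise ValueError(f"only {n} pairwise-complete sessions (< {min_n})")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return AssocResult(var_a=var_a, var_b=var_b, r=0.0, t=0.0, p=1.0,
                           order=(0, 0, 0), n=n, class_a=class_a,
                           class_b=class_b, coef=0.0)
    r = float(np.corrcoef(x, y)[0, 1])
    d = _kpss_d(y)
    if d == 1 and n < min_n + 1:
        d = 0
    X = np.column_stack([np.ones(n), x])
    beta, tvals, pvals, order = arma_error_regression(y, X, d=d,
                                                      max_p=max_p, max_q=max_q)
    return AssocResult(var_a=var_a, var_b=var_b, r=r, t=float(tvals[1]),
                       p=float(pvals[1]), order=order, n=n,
                       class_a=class_a, class_b=class_b, coef=float(beta[1]))


def bh_fdr(pvals, q: float = 0.1):
    """Benjamini-Hochberg step-up; returns (reject flags, p threshold)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")[:4]
    thresh = float(pvals[reject].max()) if reject.any() else 0.0
    return reject, thresh


def scan_pairs(table_a: pd.DataFrame, table_b: pd.DataFrame,
               min_abs_r: float = 0.2, q: float = 0.1, min_n: int = MIN_N,
               classes_a: dict | None = None, classes_b: dict | None = None
               ) -> pd.DataFrame:
    """All cross pairs tested bivariately, with BH-FDR and the |r| gate.

    Significance requires both a BH pass (at ``q``, across this scan's
    p-values) and |Pearson r| > ``min_abs_r``.  A Bonferroni-corrected
    p-value over the scan is also reported for headline-table use.  Pairs
    with too few jointly observed sessions are skipped.
    """
    idx = table_a.index.intersection(table_b.index)
    a = table_a.loc[idx]
    b = table_b.loc[idx]
    classes_a = classes_a or {}
    classes_b = classes_b or {}
    rows = []
    for ca in a.columns:
        for cb in b.columns:
            if ca == cb and table_a is table_b:
                continue
            try:
                res = arima_assoc(a[ca].values, b[cb].values, min_n=min_n,
                                  var_a=str(ca), var_b=str(cb),
                                  class_a=classes_a.get(ca, ""),
                                  class_b=classes_b.get(cb, ""))
            except ValueError:
                continue
            rows.append(res)
    if not rows:
        return pd.DataFrame(columns=["class_a", "var_a", "class_b", "var_b",
                                     "r", "t", "n", "p", "p_bh",
                                     "p_bonferroni", "significant"])
    df = pd.DataFrame({
        "class_a": [r.class_a for r in rows],
        "var_a": [r.var_a for r in rows],
        "class_b": [r.class_b for r in rows],
        "var_b": [r.var_b for r in rows],
        "r": [r.r for r in rows],
        "t": [r.t for r in rows],
        "n": [r.n for r in rows],
        "p": [r.p for r in rows],
        "order": [r.order for r in rows],
    })
    reject, _ = bh_fdr(df["p"].values, q=q)
    m = len(df)
    df["p_bh"] = np.minimum(1.0, df["p"] * m
                            / stats.rankdata(df["p"], method="max"))
    # enforce step-up monotonicity of adjusted values
    order = np.argsort(df["p"].values)[::-1]
    running = 1.0
    adj = df["p_bh"].values.copy()
    for i in order:
        running = min(running, adj[i])
        adj[i] = running
    df["p_bh"] = adj
    df["p_bonferroni"] = np.minimum(1.0, df["p"] * m)
    df["significant"] = reject & (df["r"].abs() > min_abs_r)
    return df


def replication_power(r: float, power: float = 0.80, alpha: float = 0.05
                      ) -> tuple[float, int]:
    """Sessions needed to detect a correlation of magnitude r.

    Power of the two-sided test of zero correlation is approximated on the
    Fisher-z scale with the small-sample bias correction
    ``atanh(r) + r / (2 (n - 1))`` and the null critical correlation taken
    from the t distribution at n - 2 df.  Returns the continuous solution
    and its nearest-integer rounding.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("r must be in (0, 1)")
    if not (0.0 < power < 1.0):
        raise ValueError("power must be in (0, 1)")

    def pw(n: float) -> float:
        df = n - 2.0
        tc = stats.t.isf(alpha / 2.0, df)
        rc = np.sqrt(tc ** 2 / (tc ** 2 + df))
        zr = np.arctanh(r) + r / (2.0 * (n - 1.0))
        zc = np.arctanh(rc)
        s = np.sqrt(n - 3.0)
        return float(stats.norm.sf((zc - zr) * s)
                     + stats.norm.cdf((-zc - zr) * s))

    lo, hi = 4.001, 10.0
    while pw(hi) < power and hi < 1e7:
        hi *= 2.0
    n_cont = optimize.brentq(lambda n: pw(n) - power, lo, hi, xtol=1e-8)
    return float(n_cont), int(round(n_cont))
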