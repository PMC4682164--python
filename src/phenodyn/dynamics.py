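"""Session-level connectivity summaries and longitudinal tests.

Reduces each session's connectome to mean within-network and
between-network connectivity per module (pair), builds the session
similarity matrix from vectorized connectomes, and tests linear /
quadratic session trends and fed-fasted state effects with ARMA-error
regression (order selection shared with :mod:`phenodyn.assoc`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import AssocResult, arma_error_regression
from .connectome import SessionSeries, full_correlation
from .graphs import UNASSIGNED, Partition

__all__ = [
    "network_summaries",
    "session_similarity",
    "trend_test",
    "state_effect_test",
]


def network_summaries(sessions: list[SessionSeries], p: Partition | np.ndarray,
                      fisher_z: bool = False) -> pd.DataFrame:
    """Mean within- and between-network connectivity per session.

    Columns are ``win:<m>`` for each module m and ``bw:<m>-<k>`` for each
    module pair; unassigned parcels are excluded.  Modules with fewer than
    two parcels have no within-module edges and their column is dropped
    (recorded in ``DataFrame.attrs['dropped']``).  With ``fisher_z`` the
    mean is taken on arctanh-transformed correlations and mapped back.
    """
    assignment = p.assignment if isinstance(p, Partition) else np.asarray(p)
    modules = [m for m in np.unique(assignment) if m != UNASSIGNED]
    if len(modules) < 2:
        raise ValueError("partition must have >= 2 modules")
    members = {m: np.flatnonzero(assignment == m) for m in modules}

    dropped = [f"win:{m}" for m in modules if members[m].size < 2]
    rows = []
    for s in sessions:
        corr = full_correlation(s).weights
        vals = np.arctanh(np.clip(corr, -0.999999, 0.999999)) if fisher_z else corr
        row = {}
        for m in modules:
            idx = members[m]
            if idx.size < 2:
                continue
            iu = np.triu_indices(idx.size, k=1)
            v = float(vals[np.ix_(idx, idx)][iu].mean())
            row[f"win:{m}"] = float(np.tanh(v)) if fisher_z else v
        for a_i, m in enumerate(modules):
            for k in modules[a_i + 1:]:
                v = float(vals[np.ix_(members[m], members[k])].mean())
                row[f"bw:{m}-{k}"] = float(np.tanh(v)) if fisher_z else v
        row["state"] = s.state
        rows.append(pd.Series(row, name=s.session_id))
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out


def session_similarity(sessions: list[SessionSeries]
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise similarity of session connectomes and similarity to the mean.

    Similarity is the Pearson correlation between the vectorized upper
    triangles of the per-session full-correlation connectomes.
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    ids = [s.session_id for s in sessions]
    vecs = []
    for s in sessions:
        c = full_correlation(s)
        vecs.append(c.upper_values())
    mat = np.vstack(vecs)
    sim = np.corrcoef(mat)
    mean_vec = mat.mean(axis=0)
    to_mean = np.array([np.corrcoef(v, mean_vec)[0, 1] for v in mat])
    return (pd.DataFrame(sim, index=ids, columns=ids),
            pd.Series(to_mean, index=ids, name="similarity_to_mean"))


def _clean(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    return y[ok], np.flatnonzero(ok)


def trend_test(y, kind: str = "linear", min_n: int = 10) -> dict:
    """Test for a session trend with ARMA errors.

    ``kind='linear'`` regresses on the session index; ``kind='polynomial'``
    adds an orthogonalized quadratic term and reports the test of that
    term.  Missing sessions leave gaps in the regressor (session index is
    kept, the series is compacted).  Returns coef/t/p for the tested term
    plus the selected ARMA order.
    """
    yv, idx = _clean(y)
    n = yv.size
    if n == 0:
        raise ValueError("all sessions missing")
    if n < min_n:
        raise ValueError(f"only {n} non-missing sessions (< {min_n})")
    t_reg = (idx - idx.mean()) / max(len(np.asarray(y)), 1)
    if yv.std() == 0:
        return {"coef": 0.0, "t": 0.0, "p": 1.0, "order": (0, 0, 0),
                "kind": kind, "n": n}
    if kind == "linear":
        X = np.column_stack([np.ones(n), t_reg])
        test_col = 1
    elif kind == "polynomial":
        quad = t_reg ** 2
        # orthogonalize the quadratic against [1, t]
        base = np.column_stack([np.ones(n), t_reg])
        quad = quad - base @ np.linalg.lstsq(base, quad, rcond=None)[0]
        X = np.column_stack([np.ones(n), t_reg, quad])
        test_col = 2
    else:
        raise ValueError("kind must be 'linear' or 'polynomial'")
    # order selected on the response, with no residual-based refinement:
    # the trend regressor soaks up the low-frequency part of AR noise, so
    # any residual-based step under-whitens and spuriously detects trends
    beta, tvals, pvals, order = arma_error_regression(yv, X, d=0,
                                                      select_on="response",
                                                      refine=False)
    return {"coef": float(beta[test_col]), "t": float(tvals[test_col]),
            "p": float(pvals[test_col]), "order": order, "kind": kind, "n": n}


def state_effect_test(y, state_vector, min_n: int = 10,
                      var: str = "y") -> AssocResult:
    """ARMA-error regression of y on the fed/fasted factor.

    ``state_vector`` codes fasted as 1 and fed as 0, so a positive
    coefficient means fasted > fed.
    """
    y = np.asarray(y, dtype=float)
    state = np.asarray(state_vector, dtype=float)
    if y.size != state.size:
        raise ValueError("state vector length must equal session count")
    ok = np.isfinite(y) & np.isfinite(state)
    yv, sv = y[ok], state[ok]
    n = yv.size
    if n < min_n:
        raise ValueError(f"only {n} non-missing sessions (< {min_n})")
    if np.unique(sv).size < 2:
        raise ValueError("both states must be present among non-missing sessions")
    if yv.std() == 0:
        return AssocResult(var_a="state", var_b=var, r=0.0, t=0.0, p=1.0,
                           order=(0, 0, 0), n=n, coef=0.0)
    r = float(np.corrcoef(sv, yv)[0, 1])
    X = np.column_stack([np.ones(n), sv])
    # the alternating-day contrast would alias into a period-2 ARMA term
    # if the order were selected on the raw response, absorbing the effect,
    # so selection runs on the regression residuals here
    beta, tvals, pvals, order = arma_error_regression(yv, X, d=0,
                                                      select_on="residual")
    return AssocResult(var_a="state", var_b=var, r=r, t=float(tvals[1]),
                       p=float(pvals[1]), order=order, n=n,
                       coef=float(beta[1]))
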