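"""Parcellated connectome estimation.

Estimators operating on one session's parcel x timepoint matrix with a
censoring mask:

* full Pearson correlation over usable frames only;
* L1-regularized partial correlation (graphical lasso) with the
  regularization parameter found by monotone bisection so the nonzero-edge
  density hits a target (the study's 7.5% convention);
* L2 (ridge) regularized partial correlation at a fixed penalty;
* binarization at a target edge density with optional centroid-distance
  exclusion (< 30 mm pairs removed before ranking).

Partial correlations use the standard precision-matrix mapping
``rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.covariance import graphical_lasso

__all__ = [
    "SessionSeries",
    "Connectome",
    "full_correlation",
    "partial_l1_density",
    "partial_l2",
    "binarize_at_density",
    "censor_short_runs",
    "mean_connectome",
]


@dataclass
class SessionSeries:
    """One session's parcel x timepoint data plus a censoring mask.

    ``censor_mask`` is boolean per timepoint, True = usable.  At least two
    usable timepoints are required for any estimation.
    """

    parcel_ids: np.ndarray
    data: np.ndarray
    censor_mask: np.ndarray
    session_id: str = ""
    state: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape[0] != self.data.shape[1]:
            raise ValueError("censor mask length must equal timepoint count")
        if int(self.censor_mask.sum()) < 2:
            raise ValueError("need >= 2 usable timepoints")

    @property
    def usable(self) -> np.ndarray:
        return self.data[:, self.censor_mask]


@dataclass
class Connectome:
    """Symmetric parcel x parcel weight matrix with estimator metadata."""

    weights: np.ndarray
    estimator: str
    parcel_ids: np.ndarray
    density: float | None = None
    lam: float | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.weights[iu]


def censor_short_runs(mask: np.ndarray, min_run: int = 5) -> np.ndarray:
    """Censor usable segments shorter than ``min_run`` contiguous frames."""
    mask = np.asarray(mask, dtype=bool).copy()
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_run:
                mask[i:j] = False
            i = j
        else:
            i += 1
    return mask


def _censored_cov(s: SessionSeries, warn: list) -> np.ndarray:
    """Sample covariance over usable frames; constant parcels zeroed."""
    x = s.usable
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / (n - 1)
    sd = np.sqrt(np.diag(cov))
    const = sd <= 0
    if const.any():
        for i in np.flatnonzero(const):
            warn.append(f"constant parcel {s.parcel_ids[i]}: correlations set to 0")
    return cov, sd, const


def full_correlation(s: SessionSeries) -> Connectome:
    """Pearson correlation connectome computed over usable timepoints only.

    Constant parcels get zero correlation with everything, recorded as a
    warning on the returned :class:`Connectome` rather than raised.
    """
    if int(s.censor_mask.sum()) < 3:
        raise ValueError("full correlation requires >= 3 usable timepoints")
    warn: list = []
    cov, sd, const = _censored_cov(s, warn)
    denom = np.outer(sd, sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, cov / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 0.0)
    return Connectome(weights=corr, estimator="full", parcel_ids=s.parcel_ids,
                      warnings=warn)


def _precision_to_partial(prec: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return (rho + rho.T) / 2.0


def _shrunk_corr(s: SessionSeries, warn: list) -> np.ndarray:
    cov, sd, const = _censored_cov(s, warn)
    # trace-scaled ridge for numerical safety before any inversion
    cov = cov + 1e-8 * (np.trace(cov) / cov.shape[0]) * np.eye(cov.shape[0])
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


def _glasso_density(corr: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, prec = graphical_lasso(corr, alpha=lam, max_iter=200, tol=1e-5)
    iu = np.triu_indices(corr.shape[0], k=1)
    nz = np.abs(prec[iu]) > 1e-10
    return prec, float(nz.mean())


def partial_l1_density(s: SessionSeries, target_density: float = 0.075,
                       tol: float = 0.001, max_iter: int = 60) -> Connectome:
    """Sparse partial-correlation connectome at a target edge density.

    Solves the graphical-lasso objective and searches the regularization
    parameter by monotone bisection (achieved density is non-increasing in
    the penalty) until the fraction of nonzero off-diagonal precision
    entries is within ``tol`` of ``target_density``.  The achieved density
    and penalty are recorded on the result.
    """
    if not (0.0 < target_density < 1.0):
        raise ValueError("target_density must be in (0, 1)")
    warn: list = []
    corr = _shrunk_corr(s, warn)

    lo, hi = 1e-4, 1.0
    prec_lo, d_lo = _glasso_density(corr, lo)
    for _ in range(20):
        if d_lo >= target_density:
            break
        lo /= 4.0
        prec_lo, d_lo = _glasso_density(corr, lo)
    prec_hi, d_hi = _glasso_density(corr, hi)
    for _ in range(20):
        if d_hi <= target_density:
            break
        hi *= 4.0
        prec_hi, d_hi = _glasso_density(corr, hi)
    if d_lo < target_density or d_hi > target_density:
        raise RuntimeError(
            f"density target {target_density} not bracketed by "
            f"lambda in [{lo}, {hi}] (densities {d_lo}, {d_hi})")

    best = (abs(d_lo - target_density), lo, prec_lo, d_lo)
    if abs(d_hi - target_density) < best[0]:
        best = (abs(d_hi - target_density), hi, prec_hi, d_hi)
    prev_d = None
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection on the penalty scale
        prec, d = _glasso_density(corr, mid)
        if abs(d - target_density) < best[0]:
            best = (abs(d - target_density), mid, prec, d)
        if abs(d - target_density) <= tol:
            break
        if d > target_density:
            lo = mid
        else:
            hi = mid
        if prev_d is not None and hi / lo < 1 + 1e-12:
            break
        prev_d = d
    err, lam, prec, dens = best
    if err > max(tol, 2.0 / (s.data.shape[0] * (s.data.shape[0] - 1))):
        raise RuntimeError(
            f"bisection did not reach density {target_density} +- {tol} "
            f"within {max_iter} iterations; interval [{lo}, {hi}], "
            f"best achieved {dens}")
    rho = _precision_to_partial(prec)
    rho[np.abs(rho) <= 1e-10] = 0.0
    return Connectome(weights=rho, estimator="partial_l1",
                      parcel_ids=s.parcel_ids, density=dens, lam=lam,
                      warnings=warn)


def partial_l2(s: SessionSeries, lam: float = 1e-4) -> Connectome:
    """Ridge-regularized partial correlation: Omega = (R + lam I)^-1."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    warn: list = []
    corr = _shrunk_corr(s, warn)
    prec = np.linalg.inv(corr + lam * np.eye(corr.shape[0]))
    rho = _precision_to_partial(prec)
    return Connectome(weights=rho, estimator="partial_l2",
                      parcel_ids=s.parcel_ids, lam=lam, warnings=warn)


def binarize_at_density(c: Connectome, density: float,
                        exclusion_mm: float | None = None,
                        centroids: np.ndarray | None = None) -> Connectome:
    """Keep the top ``density`` fraction of pairs (by signed weight) as edges.

    Pairs with centroids closer than ``exclusion_mm`` are removed before
    ranking.  Ties are broken toward the smaller (i, j) index pair so the
    result is deterministic.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    n = c.n_parcels
    iu, ju = np.triu_indices(n, k=1)
    w = c.weights[iu, ju]
    eligible = np.ones(w.size, dtype=bool)
    if exclusion_mm is not None:
        if centroids is None:
            raise ValueError("exclusion_mm requires centroids")
        dist = squareform(pdist(np.asarray(centroids, dtype=float)))
        eligible = dist[iu, ju] >= exclusion_mm
    m = int(round(density * iu.size))
    if m > int(eligible.sum()):
        raise ValueError(
            f"density {density} requests {m} edges but only "
            f"{int(eligible.sum())} eligible pairs remain after exclusion")
    order = np.lexsort((ju, iu, -w))
    order = order[eligible[order]][:m]
    adj = np.zeros((n, n))
    adj[iu[order], ju[order]] = 1.0
    adj = adj + adj.T
    return Connectome(weights=adj, estimator=c.estimator,
                      parcel_ids=c.parcel_ids, density=density,
                      warnings=list(c.warnings))


def mean_connectome(connectomes: list[Connectome]) -> Connectome:
    """Element-wise mean of same-shape connectomes (mean-then-threshold path)."""
    if not connectomes:
        raise ValueError("no connectomes to average")
    w = np.mean([c.weights for c in connectomes], axis=0)
    return Connectome(weights=w, estimator=connectomes[0].estimator,
                      parcel_ids=connectomes[0].parcel_ids)


def read_connectome_tsv(path) -> Connectome:
    """Read a square TSV with parcel header row/column."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Connectome(weights=df.values, estimator="full",
                      parcel_ids=np.asarray(df.index))


def write_connectome_tsv(c: Connectome, path) -> None:
    import pandas as pd
    ids = [str(i) for i in c.parcel_ids]
    pd.DataFrame(c.weights, index=ids, columns=ids).to_csv(path, sep="\t")
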