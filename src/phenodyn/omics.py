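"""Gene-count preprocessing, coexpression modules, metabolite clustering.

The expression side follows the standard bulk RNA-seq path: median-of-ratios
size factors, expression filtering (mean in [4, 10000] after normalization,
small RNAs removed), a closed-form variance-stabilizing transform under a
fitted dispersion-mean relation alpha(mu) = a1/mu + a0, and nuisance
regression against quality covariates plus global expression components.
Coexpression modules come from a weighted-network analysis: biweight
midcorrelation, scale-free soft thresholding, topological overlap,
average-linkage clustering with a static height cut, and per-module
eigengenes (first principal components, sign-aligned).  Metabolite peak
heights are normalized per session and clustered by affinity propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ModuleSet",
    "size_factors",
    "filter_genes",
    "vst",
    "nuisance_regress",
    "bicor",
    "bicor_matrix",
    "pick_soft_power",
    "tom_similarity",
    "coexpression_modules",
    "project_eigengenes",
    "metab_normalize",
    "affinity_propagation",
]

GREY = 0  # unassigned module label


@dataclass
class ModuleSet:
    """Feature -> module membership (0 = unassigned) with eigengenes."""

    membership: pd.Series
    eigengenes: pd.DataFrame          # modules x sessions, unit variance
    variance_explained: pd.Series
    loadings: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list:
        return [m for m in sorted(self.membership.unique()) if m != GREY]


# ---------------------------------------------------------------------------
# count preprocessing

def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios library-size factors.

    factor_j = median over all-nonzero genes of count_gj / geometric mean of
    gene g.  With no all-nonzero gene, pass a positive ``pseudocount``.
    """
    mat = counts.values.astype(float) + pseudocount
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    ok = np.all(np.isfinite(logs), axis=1)
    if not ok.any():
        raise ValueError("no gene has nonzero counts in every session; "
                         "consider the pseudocount option")
    geo = np.exp(logs[ok].mean(axis=1))
    ratios = mat[ok] / geo[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


def filter_genes(counts: pd.DataFrame, min_mean: float = 4.0,
                 max_mean: float = 10000.0, small_rna: pd.Series | None = None,
                 use_normalized: bool = True,
                 factors: pd.Series | None = None) -> pd.DataFrame:
    """Drop small RNAs, then genes with mean count outside [min_mean, max_mean].

    Boundaries are inclusive (a mean of exactly 4 is kept).  Means are taken
    on size-factor-normalized counts by default (``use_normalized=False``
    uses raw means).  Removal counts per category are recorded in
    ``result.attrs['removed']``.
    """
    if small_rna is None:
        small_rna = counts.attrs.get("small_rna")
    if small_rna is None:
        small_rna = pd.Series(False, index=counts.index)
    small_rna = small_rna.reindex(counts.index).fillna(False).astype(bool)

    if use_normalized:
        if factors is None:
            factors = size_factors(counts)
        mat = counts.values / factors.values[None, :]
    else:
        mat = counts.values.astype(float)
    means = mat.mean(axis=1)

    keep = ~small_rna.values & (means >= min_mean) & (means <= max_mean)
    removed = {
        "small_rna": int(small_rna.sum()),
        "below": int(np.sum(~small_rna.values & (means < min_mean))),
        "above": int(np.sum(~small_rna.values & (means > max_mean))),
    }
    out = counts.loc[keep].copy()
    if out.shape[0] == 0:
        raise ValueError("no genes pass the expression filter")
    out.attrs = dict(counts.attrs)
    out.attrs["removed"] = removed
    if "small_rna" in out.attrs:
        out.attrs["small_rna"] = small_rna.loc[out.index]
    return out


def _fit_dispersion(norm: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a1/mu + a0 to per-gene moment dispersions."""
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    ok = mu > 0
    mu, var = mu[ok], var[ok]
    alpha = (var - mu) / mu ** 2
    ok = alpha > 0
    if ok.sum() < 3:
        return 0.0, -1.0
    mu, alpha = mu[ok], alpha[ok]
    X = np.column_stack([np.ones(mu.size), 1.0 / mu])
    # least absolute-ish: trim gross outliers then OLS
    coef, _, _, _ = np.linalg.lstsq(X, alpha, rcond=None)
    pred = X @ coef
    resid = alpha - pred
    keep = np.abs(resid) <= 3.0 * np.std(resid) + 1e-12
    if keep.sum() >= 3:
        coef, _, _, _ = np.linalg.lstsq(X[keep], alpha[keep], rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    return a0, max(a1, 0.0)


def vst(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilizing transform of normalized counts.

    Under the negative-binomial variance v(mu) = mu + alpha(mu) mu^2 with
    alpha(mu) = a1/mu + a0, the antiderivative of 1 / sqrt(v) has the closed
    form

        vst(x) = log2( (1 + a1 + 2 a0 x
                        + 2 sqrt(a0 x (1 + a1 + a0 x))) / (4 a0) )

    which approaches log2(x) for large counts.  If the fitted a0 is not
    positive the transform degenerates and a shifted log2(x + 1) is used
    instead (recorded in ``attrs['vst_fallback']``).
    """
    if factors is None:
        factors = size_factors(counts)
    if np.any(factors.values <= 0):
        raise ValueError("size factors must be positive")
    norm = counts.values / factors.values[None, :]
    a0, a1 = _fit_dispersion(norm)
    out_attrs = {"dispersion_a0": a0, "dispersion_a1": a1}
    if a0 <= 0:
        warnings.warn("degenerate dispersion fit (a0 <= 0); "
                      "falling back to shifted log2", RuntimeWarning)
        vals = np.log2(norm + 1.0)
        out_attrs["vst_fallback"] = True
    else:
        x = norm
        vals = np.log2((1.0 + a1 + 2.0 * a0 * x
                        + 2.0 * np.sqrt(a0 * x * (1.0 + a1 + a0 * x)))
                       / (4.0 * a0))
        out_attrs["vst_fallback"] = False
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    out.attrs = dict(counts.attrs)
    out.attrs.update(out_attrs)
    return out


def nuisance_regress(x: pd.DataFrame, covariates: np.ndarray | pd.DataFrame | None,
                     n_pcs: int = 3) -> pd.DataFrame:
    """Residualize each feature on covariates plus global expression PCs.

    The principal components are session-level scores of the full feature
    matrix (right singular vectors of the centred matrix), capturing global
    technical variation.  Residuals are orthogonal to every regressor.
    """
    mat = x.values.astype(float)
    n_feat, n_sess = mat.shape
    cols = [np.ones(n_sess)]
    names = ["intercept"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            names.append(f"cov{j}")
    if n_pcs > 0:
        centred = mat - mat.mean(axis=1, keepdims=True)
        centred = centred - centred.mean(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        for j in range(min(n_pcs, vt.shape[0])):
            cols.append(vt[j])
            names.append(f"pc{j + 1}")
    design = np.column_stack(cols)
    if n_sess < design.shape[1] + 2:
        raise ValueError("not enough sessions for the nuisance design")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        r = np.abs(np.diag(np.linalg.qr(design, mode="r")))
        bad = [names[i] for i in np.flatnonzero(r < 1e-10 * r.max())]
        raise ValueError(f"rank-deficient nuisance design; collinear: {bad}")
    beta, _, _, _ = np.linalg.lstsq(design, mat.T, rcond=None)
    resid = mat - (design @ beta).T
    out = pd.DataFrame(resid, index=x.index, columns=x.columns)
    out.attrs = dict(x.attrs)
    return out


# ---------------------------------------------------------------------------
# robust correlation and network construction

def _biweight(x: np.ndarray) -> np.ndarray | None:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return (x - med) * w


def bicor(x, y) -> tuple[float, bool]:
    """Biweight midcorrelation of two vectors.

    Returns ``(value, fallback)`` where ``fallback`` is True when a zero
    median absolute deviation forced a Pearson fallback.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("bicor needs >= 4 observations")
    xt = _biweight(x)
    yt = _biweight(y)
    if xt is None or yt is None:
        return float(np.corrcoef(x, y)[0, 1]), True
    denom = np.sqrt((xt @ xt) * (yt @ yt))
    if denom == 0:
        return 0.0, True
    return float(np.clip((xt @ yt) / denom, -1.0, 1.0)), False


def bicor_matrix(x: np.ndarray) -> np.ndarray:
    """Row-by-row biweight midcorrelation matrix (Pearson rows flagged by MAD=0)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    zero = (mad[:, 0] == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (x - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    xt = (x - med) * w
    if zero.any():  # Pearson fallback rows
        xc = x[zero] - x[zero].mean(axis=1, keepdims=True)
        xt[zero] = xc
    norms = np.sqrt(np.sum(xt ** 2, axis=1))
    norms[norms == 0] = 1.0
    c = (xt / norms[:, None]) @ (xt / norms[:, None]).T
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def pick_soft_power(sim: np.ndarray, powers=range(1, 21),
                    r2_target: float = 0.8, n_bins: int = 10
                    ) -> tuple[int, pd.DataFrame]:
    """Soft-threshold power by the scale-free topology criterion.

    For each power the adjacency is |sim|^power; the connectivity
    distribution is binned and the signed R^2 of the log-log
    degree-frequency fit computed (sign flipped when the slope is
    positive).  Returns the smallest power reaching ``r2_target`` (or the
    argmax as fallback) plus a diagnostics table.
    """
    sim = np.asarray(sim, dtype=float)
    rows = []
    for beta in powers:
        adj = np.abs(sim) ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        if np.allclose(k, k[0]):
            rows.append((beta, 0.0, 0.0))
            continue
        hist, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            rows.append((beta, 0.0, 0.0))
            continue
        lx, ly = np.log10(centers[ok]), np.log10(hist[ok])
        slope, intercept = np.polyfit(lx, ly, 1)
        r = np.corrcoef(lx, ly)[0, 1]
        signed_r2 = -np.sign(slope) * r ** 2
        rows.append((beta, float(signed_r2), float(slope)))
    diag = pd.DataFrame(rows, columns=["power", "signed_r2", "slope"])
    passing = diag[diag["signed_r2"] >= r2_target]
    if len(passing):
        power = int(passing["power"].iloc[0])
    else:
        power = int(diag.loc[diag["signed_r2"].idxmax(), "power"])
    return power, diag


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency (zero diagonal).

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    unit diagonal.
    """
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, (shared + a) / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def _eigengene(block: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """First principal component of standardized feature profiles.

    Returns (scores with unit variance, variance explained, loadings);
    the sign is fixed so the mean loading is positive.
    """
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (block - block.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    loadings = u[:, 0] * s[0]
    if loadings.mean() < 0:
        scores = -scores
        loadings = -loadings
    var_exp = float(s[0] ** 2 / np.sum(s ** 2)) if s.sum() > 0 else 0.0
    ssd = scores.std()
    if ssd > 0:
        scores = scores / ssd
    return scores, var_exp, loadings


def coexpression_modules(x: pd.DataFrame, power: int = 8,
                         min_module: int = 30,
                         cut_height: float = 0.99) -> ModuleSet:
    """Extract coexpression modules from a residualized expression matrix.

    Adjacency |bicor|^power -> topological overlap -> average-linkage
    clustering of 1 - TOM -> static cut at ``cut_height`` of the relative
    merge-height range (h_min + cut_height * (h_max - h_min); the absolute
    heights concentrate near 1 once weak adjacencies are raised to a soft
    power, so the cut is taken on the relative scale).  Clusters smaller
    than ``min_module`` go to the unassigned (grey, 0) module.  Eigengenes
    are per-module first principal components with positive mean loading
    and unit variance.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    mat = x.values.astype(float)
    sim = bicor_matrix(mat)
    adj = np.abs(sim) ** power
    tom = tom_similarity(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    h = z[:, 2]
    cut = float(h.min() + cut_height * (h.max() - h.min()))
    raw = fcluster(z, t=cut, criterion="distance")

    labels = np.zeros(mat.shape[0], dtype=int)
    sizes = pd.Series(raw).value_counts()
    big = [lab for lab, sz in sizes.items() if sz >= min_module]
    big.sort(key=lambda lab: (-sizes[lab], lab))
    for new, lab in enumerate(big, start=1):
        labels[raw == lab] = new
    if not big:
        warnings.warn("no module reached min_module size; all features grey",
                      RuntimeWarning)

    membership = pd.Series(labels, index=x.index, name="module")
    eig = {}
    var_exp = {}
    loadings = {}
    for m in sorted(set(labels) - {GREY}):
        block = mat[labels == m]
        scores, ve, load = _eigengene(block)
        eig[m] = scores
        var_exp[m] = ve
        loadings[m] = pd.Series(load, index=x.index[labels == m])
    eigengenes = pd.DataFrame(eig, index=x.columns).T
    eigengenes.index.name = "module"
    return ModuleSet(membership=membership, eigengenes=eigengenes,
                     variance_explained=pd.Series(var_exp, dtype=float),
                     loadings=loadings)


def project_eigengenes(external_expr: pd.DataFrame, modules: ModuleSet,
                       covariates=None, n_pcs: int = 3,
                       min_overlap: float = 0.5
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Apply existing module memberships to a new expression matrix.

    The external matrix is residualized with its own nuisance settings,
    then per-module first principal components are extracted over the
    overlapping genes.  Modules with gene-id overlap below ``min_overlap``
    are skipped with a warning.  Returns (eigengene scores, overlap
    fraction per module).
    """
    resid = nuisance_regress(external_expr, covariates, n_pcs=n_pcs)
    eig = {}
    overlaps = {}
    for m in modules.module_ids:
        genes = modules.membership.index[modules.membership == m]
        present = genes.intersection(resid.index)
        frac = len(present) / len(genes) if len(genes) else 0.0
        overlaps[m] = frac
        if frac < min_overlap:
            warnings.warn(f"module {m}: only {frac:.0%} of genes present; "
                          "skipped", RuntimeWarning)
            continue
        scores, _, _ = _eigengene(resid.loc[present].values)
        eig[m] = scores
    scores_df = pd.DataFrame(eig, index=resid.columns).T
    scores_df.index.name = "module"
    return scores_df, pd.Series(overlaps, name="overlap")


# ---------------------------------------------------------------------------
# metabolomics

def metab_normalize(peaks: pd.DataFrame) -> pd.DataFrame:
    """Divide each session's peak heights by that session's mean height."""
    vals = peaks.values.astype(float)
    if np.any(vals <= 0):
        raise ValueError("peak heights must be positive")
    return pd.DataFrame(vals / vals.mean(axis=0, keepdims=True),
                        index=peaks.index, columns=peaks.columns)


def affinity_propagation(sim: np.ndarray, damping: float = 0.9,
                         preference: float | None = None, seed: int = 0,
                         max_iter: int = 1000, convergence_iter: int = 100
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exemplar clustering by responsibility/availability message passing.

    ``sim`` is a square similarity matrix; the preference defaults to the
    median similarity.  Every point is assigned to exactly one exemplar and
    exemplars are assigned to themselves.  Raises on non-convergence with
    advice to raise the damping.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity matrix must be square")
    if sim.shape[0] == 1:
        return np.array([0]), np.array([0])
    pref = float(np.median(sim)) if preference is None else preference
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(affinity="precomputed", damping=damping,
                                     preference=pref, max_iter=max_iter,
                                     convergence_iter=convergence_iter,
                                     random_state=seed).fit(sim)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                "affinity propagation oscillated without converging; "
                "try a higher damping value") from exc
    labels = ap.labels_
    exemplars = ap.cluster_centers_indices_
    if exemplars is None or len(exemplars) == 0:
        raise RuntimeError(
            "affinity propagation found no exemplars; try a higher damping")
    return np.asarray(exemplars), np.asarray(labels)
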