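"""Synthetic multi-domain longitudinal data with planted ground truth.

Emulates the statistical structure of a dense single-subject phenotyping
study: parcellated resting-state sessions with censoring, a binary
fed/fasted session factor, slow session trends, negative-binomial gene
counts organised into coexpression modules, clustered metabolite
concentrations, autocorrelated behavioural series with missingness, and
planted cross-domain associations of known effect size.

The parcel time series follow a factor model: parcel ``i`` in network ``m``
at session ``s`` is

    x_i(t) = sqrt(b) g(t) + sqrt(w_ms - b) f_m(t) + sqrt(1 - w_ms) e_i(t)

with unit-variance global factor ``g``, network factor ``f_m`` and noise
``e_i``.  The implied parcel-parcel correlation is ``w_ms`` inside network
``m`` and ``b`` between networks.  Session-level effects (fed/fasted
contrast, linear/quadratic trends, an AR(1) session noise term) enter by
modulating the within-network level ``w_ms``, so downstream summary
statistics inherit exactly the planted longitudinal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import SessionSeries, Connectome

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_parcel_sessions",
    "gen_structural",
    "gen_omics_and_behavior",
    "write_dataset",
]

UNASSIGNED = -1


class ParameterizationError(ValueError):
    """Raised when a configuration implies an infeasible correlation structure."""


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults emulate the study's data inventory.

    Correlation levels must satisfy ``0 <= between < within < 1`` and remain
    feasible after session modulation (state effect, trends, session noise).
    """

    n_parcels: int = 630
    n_networks: int = 12
    n_sessions: int = 84
    timepoints_per_session: int = 500
    within_network_corr: float = 0.35
    between_network_corr: float = 0.08
    ar1_coef: float = 0.5
    state_effect_size: float = 0.05
    trend_slopes: float | Sequence[float] = 0.0
    quad_coefs: float | Sequence[float] = 0.0
    n_genes: int = 2000
    n_gene_modules: int = 10
    nb_dispersion: float = 0.2
    n_metabolites: int = 106
    n_metab_clusters: int = 15
    planted_associations: tuple = ()
    missing_rate: float = 0.15
    censor_rate: float = 0.03
    session_noise_sd: float = 0.02
    small_rna_frac: float = 0.15
    extreme_mean_frac: float = 0.02
    n_behavior: int = 10
    n_omics_sessions: int | None = None  # default: min(48, n_sessions)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_parcels", "n_networks", "n_sessions",
                     "timepoints_per_session", "n_genes", "n_gene_modules",
                     "n_metabolites", "n_metab_clusters", "n_behavior"):
            if getattr(self, name) <= 0:
                raise ParameterizationError(f"{name} must be positive")
        if not (0.0 <= self.between_network_corr < 1.0):
            raise ParameterizationError("between_network_corr must be in [0, 1)")
        if not (0.0 <= self.within_network_corr < 1.0):
            raise ParameterizationError("within_network_corr must be in [0, 1)")
        if self.within_network_corr < self.between_network_corr:
            raise ParameterizationError(
                "factor model requires within_network_corr >= between_network_corr")
        if not (-1.0 < self.ar1_coef < 1.0):
            raise ParameterizationError("ar1_coef must be in (-1, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterizationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ParameterizationError("censor_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ParameterizationError("nb_dispersion must be >= 0")
        if self.n_omics_sessions is None:
            object.__setattr__(self, "n_omics_sessions",
                               min(48, self.n_sessions))
        if self.n_omics_sessions > self.n_sessions:
            raise ParameterizationError("n_omics_sessions cannot exceed n_sessions")

    def _per_network(self, value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(self.n_networks, float(arr))
        if arr.shape != (self.n_networks,):
            raise ParameterizationError(
                f"per-network parameter has shape {arr.shape}, "
                f"expected ({self.n_networks},)")
        return arr


@dataclass
class GroundTruth:
    """Planted structure recorded by the generators; the oracle for tests."""

    parcel_partition: np.ndarray
    hemisphere_labels: np.ndarray          # 'L'/'R' per parcel
    centroids: np.ndarray                  # (n_parcels, 3), mm
    state_vector: np.ndarray               # 1 = fasted, 0 = fed, per session
    trend_design: np.ndarray               # centred session regressor
    within_targets: np.ndarray             # (n_networks, n_sessions) planted w_ms
    planted_associations: tuple = ()
    gene_module_membership: np.ndarray | None = None
    metab_cluster_membership: np.ndarray | None = None
    gene_module_factors: np.ndarray | None = None   # (n_modules, n_omics_sessions)
    metab_cluster_factors: np.ndarray | None = None
    omics_sessions: np.ndarray | None = None
    filter_counts: dict = field(default_factory=dict)


def _ar1_series(n: int, coef: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) of length n with marginal standard deviation sd."""
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - coef ** 2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = coef * x[i - 1] + rng.normal(0.0, innov_sd)
    return x


def _geometric_run_mask(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Censoring mask (True = usable) built from geometric runs of bad frames.

    Bad stretches start with probability chosen to give an expected censored
    fraction ``rate``, and last for a geometric number of frames (mean 3), so
    short usable segments occur and exercise the contiguous-frames rule.
    """
    mask = np.ones(n, dtype=bool)
    if rate <= 0:
        return mask
    mean_run = 3.0
    p_start = rate / (mean_run * (1.0 - rate) + rate)
    i = 0
    while i < n:
        if rng.random() < p_start:
            run = rng.geometric(1.0 / mean_run)
            mask[i:i + run] = False
            i += run
        else:
            i += 1
    return mask


def _parcel_geometry(cfg: SimConfig, rng: np.random.Generator):
    """Partition parcels into networks and scatter centroids in mm space."""
    base = np.arange(cfg.n_parcels) % cfg.n_networks
    partition = np.sort(base)
    net_centers = rng.uniform([-55.0, -90.0, -40.0], [55.0, 60.0, 70.0],
                              size=(cfg.n_networks, 3))
    centroids = net_centers[partition] + rng.normal(0.0, 18.0, size=(cfg.n_parcels, 3))
    # networks span both hemispheres: mirror a random half of each network
    flip = rng.random(cfg.n_parcels) < 0.5
    centroids[:, 0] = np.abs(centroids[:, 0])
    centroids[flip, 0] *= -1.0
    hemis = np.where(centroids[:, 0] < 0, "L", "R")
    return partition, centroids, hemis


def _session_within_targets(cfg: SimConfig, state: np.ndarray,
                            trend: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Planted within-network correlation per (network, session)."""
    slopes = cfg._per_network(cfg.trend_slopes)
    quads = cfg._per_network(cfg.quad_coefs)
    w = np.full((cfg.n_networks, cfg.n_sessions), cfg.within_network_corr)
    quad_reg = trend ** 2 - np.mean(trend ** 2)
    for m in range(cfg.n_networks):
        w[m] += slopes[m] * trend + quads[m] * quad_reg
        w[m] += _ar1_series(cfg.n_sessions, cfg.ar1_coef, cfg.session_noise_sd, rng)
    w[:, :] += cfg.state_effect_size * state[None, :]
    b = cfg.between_network_corr
    if np.any(w >= 0.995) or np.any(w < b):
        raise ParameterizationError(
            "session modulation drives within-network correlation outside "
            f"[{b}, 1); reduce effect sizes, trends or session noise")
    return w


def gen_parcel_sessions(cfg: SimConfig) -> tuple[list[SessionSeries], GroundTruth]:
    """Generate per-session parcel time series plus the ground-truth record.

    Returns a list of :class:`SessionSeries` (one per session, with censoring
    masks) and a :class:`GroundTruth` holding the planted partition, geometry,
    state schedule, trend design and realized within-network correlation
    targets.  Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    partition, centroids, hemis = _parcel_geometry(cfg, rng)

    # fed/fasted alternates deterministically (Tuesday/Thursday schedule)
    state = (np.arange(cfg.n_sessions) % 2 == 0).astype(int)
    trend = (np.arange(cfg.n_sessions) - (cfg.n_sessions - 1) / 2.0)
    trend = trend / max(cfg.n_sessions, 1)

    w_targets = _session_within_targets(cfg, state, trend, rng)
    b = cfg.between_network_corr
    T = cfg.timepoints_per_session
    sessions = []
    for s in range(cfg.n_sessions):
        g = rng.standard_normal(T)
        f = rng.standard_normal((cfg.n_networks, T))
        eps = rng.standard_normal((cfg.n_parcels, T))
        w_ms = w_targets[:, s]
        a_net = np.sqrt(np.maximum(w_ms - b, 0.0))
        a_noise = np.sqrt(np.maximum(1.0 - w_ms, 0.0))
        data = (np.sqrt(b) * g[None, :]
                + a_net[partition, None] * f[partition]
                + a_noise[partition, None] * eps)
        mask = _geometric_run_mask(T, cfg.censor_rate, rng)
        sessions.append(SessionSeries(
            parcel_ids=np.arange(cfg.n_parcels),
            data=data,
            censor_mask=mask,
            session_id=f"ses{s:03d}",
            state="fasted" if state[s] else "fed",
        ))

    truth = GroundTruth(
        parcel_partition=partition,
        hemisphere_labels=hemis,
        centroids=centroids,
        state_vector=state,
        trend_design=trend,
        within_targets=w_targets,
        planted_associations=tuple(cfg.planted_associations),
    )
    return sessions, truth


# ---------------------------------------------------------------------------
# structural connectome generator

def planted_functional_edges(truth: GroundTruth, density: float,
                             within: float, between: float) -> set[tuple[int, int]]:
    """Top-``density`` edge set of the planted (noise-free) correlation model.

    Within-network pairs all share one correlation level, so ties are broken
    deterministically by (i, j) ordering.
    """
    part = truth.parcel_partition
    n = part.size
    iu, ju = np.triu_indices(n, k=1)
    w = np.where(part[iu] == part[ju], within, between)
    m = int(round(density * iu.size))
    order = np.lexsort((ju, iu, -w))[:m]
    return set(zip(iu[order].tolist(), ju[order].tolist()))


def gen_structural(truth: GroundTruth, agreement: float, density: float,
                   seed: int, inter_hemi_weight: float = 1.0,
                   within: float = 0.35, between: float = 0.08) -> Connectome:
    """Nonnegative tract-count matrix with tunable functional agreement.

    A fraction ``agreement`` of the structural edges is drawn from the
    planted functional edge set at the same density; the rest are placed
    uniformly at random among the remaining pairs.  ``inter_hemi_weight``
    thins interhemispheric candidates (0 removes them entirely, emulating
    tractography's failure to find interhemispheric connections).
    """
    if not (0.0 <= agreement <= 1.0):
        raise ValueError("agreement must be in [0, 1]")
    if not (0.0 < density <= 1.0):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    part = truth.parcel_partition
    n = part.size
    func = planted_functional_edges(truth, density, within, between)
    iu, ju = np.triu_indices(n, k=1)
    all_pairs = list(zip(iu.tolist(), ju.tolist()))
    m = int(round(density * len(all_pairs)))

    hemi = truth.hemisphere_labels

    def keep(pair):
        if inter_hemi_weight >= 1.0:
            return True
        if hemi[pair[0]] == hemi[pair[1]]:
            return True
        return rng.random() < inter_hemi_weight

    func_list = sorted(func)
    nonfunc = [p for p in all_pairs if p not in func]
    k_func = int(round(agreement * m))
    chosen = []
    idx = rng.permutation(len(func_list))
    for i in idx:
        if len(chosen) >= k_func:
            break
        if keep(func_list[i]):
            chosen.append(func_list[i])
    idx = rng.permutation(len(nonfunc))
    for i in idx:
        if len(chosen) >= m:
            break
        if keep(nonfunc[i]):
            chosen.append(nonfunc[i])

    counts = np.zeros((n, n))
    for (i, j) in chosen:
        c = 1 + rng.poisson(20)
        counts[i, j] = counts[j, i] = c
    return Connectome(weights=counts, estimator="structural",
                      parcel_ids=np.arange(n))


# ---------------------------------------------------------------------------
# omics and behaviour

def _resolve_anchor(name: str, truth: GroundTruth) -> np.ndarray | None:
    """Map a planted-association variable name to its session series."""
    kind, _, idx = name.partition(":")
    if kind == "network":
        return truth.within_targets[int(idx)]
    return None


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _tied_factor(name: str, cfg: SimConfig, truth: GroundTruth,
                 sess_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent factor for ``name``, tied to an anchor if an association is planted."""
    for (a, b, r) in cfg.planted_associations:
        other = None
        if a == name:
            other = b
        elif b == name:
            other = a
        if other is None:
            continue
        anchor = _resolve_anchor(other, truth)
        if anchor is not None:
            z = _standardize(anchor[sess_idx])
            noise = _standardize(rng.standard_normal(sess_idx.size))
            return float(r) * z + np.sqrt(max(1.0 - r ** 2, 0.0)) * noise
    return _ar1_series(sess_idx.size, cfg.ar1_coef, 1.0, rng)


def _nb_counts(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draws with var = mu + alpha mu^2 (Poisson when alpha ~ 0)."""
    if alpha < 1e-8:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    return rng.poisson(lam)


def gen_omics_and_behavior(cfg: SimConfig, truth: GroundTruth
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene counts, metabolite peak heights and behaviour, sharing latents.

    Gene counts are negative-binomial around module-specific latent factors;
    module factors (and behaviour series) named in
    ``cfg.planted_associations`` are tied to the planted network summaries at
    the configured correlation.  A subset of genes is flagged small-RNA and
    another subset is given extreme means so the expression filters have
    known removal counts (recorded in ``truth.filter_counts``).  Metabolites
    are log-normal around cluster exemplar profiles; behaviour series are
    AR(1) with MCAR missingness at ``cfg.missing_rate``.  Ground truth is
    updated in place with memberships and realized factors.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    sess_idx = np.sort(rng.choice(cfg.n_sessions, size=cfg.n_omics_sessions,
                                  replace=False))
    sess_ids = [f"ses{s:03d}" for s in sess_idx]
    ns = sess_idx.size

    # ---- genes -----------------------------------------------------------
    membership = np.sort(np.arange(cfg.n_genes) % cfg.n_gene_modules)
    factors = np.vstack([
        _tied_factor(f"gene_module:{k}", cfg, truth, sess_idx, rng)
        for k in range(cfg.n_gene_modules)])

    base_mean = np.exp(rng.normal(np.log(60.0), 1.0, size=cfg.n_genes))
    loading = rng.uniform(0.35, 0.6, size=cfg.n_genes)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_genes, p=[0.25, 0.75])
    lib = np.exp(rng.normal(0.0, 0.25, size=ns))

    n_small = int(round(cfg.small_rna_frac * cfg.n_genes))
    n_extreme = int(round(cfg.extreme_mean_frac * cfg.n_genes))
    perm = rng.permutation(cfg.n_genes)
    small_rna = np.zeros(cfg.n_genes, dtype=bool)
    small_rna[perm[:n_small]] = True
    lo = perm[n_small:n_small + n_extreme]
    hi = perm[n_small + n_extreme:n_small + 2 * n_extreme]
    base_mean[lo] = rng.uniform(0.2, 2.0, size=lo.size)
    base_mean[hi] = rng.uniform(3e4, 8e4, size=hi.size)

    log_mu = (np.log(base_mean)[:, None]
              + (sign * loading)[:, None] * factors[membership]
              + rng.normal(0.0, 0.15, size=(cfg.n_genes, ns)))
    mu = np.exp(log_mu) * lib[None, :]
    counts = _nb_counts(mu, cfg.nb_dispersion, rng)

    gene_ids = [f"g{g:05d}" for g in range(cfg.n_genes)]
    genes = pd.DataFrame(counts, index=gene_ids, columns=sess_ids)
    genes.attrs["small_rna"] = pd.Series(small_rna, index=gene_ids)
    genes.attrs["rin"] = pd.Series(rng.uniform(6.0, 9.5, size=ns), index=sess_ids)

    # planted filter bookkeeping on the same normalization the filter uses
    from .omics import size_factors as _size_factors
    sf = _size_factors(genes).values
    norm_mean = (counts / sf[None, :]).mean(axis=1)
    truth.filter_counts = {
        "small_rna": int(small_rna.sum()),
        "below": int(np.sum(~small_rna & (norm_mean < 4.0))),
        "above": int(np.sum(~small_rna & (norm_mean > 10000.0))),
    }

    # ---- metabolites -----------------------------------------------------
    m_membership = np.sort(np.arange(cfg.n_metabolites) % cfg.n_metab_clusters)
    m_factors = np.vstack([
        _tied_factor(f"metab_cluster:{k}", cfg, truth, sess_idx, rng)
        for k in range(cfg.n_metab_clusters)])
    m_base = rng.normal(5.0, 1.0, size=cfg.n_metabolites)
    m_load = rng.uniform(0.6, 1.0, size=cfg.n_metabolites)
    profile = (m_base[:, None] + m_load[:, None] * m_factors[m_membership]
               + rng.normal(0.0, 0.4, size=(cfg.n_metabolites, ns)))
    peaks = np.exp(0.4 * profile)
    metab = pd.DataFrame(peaks, index=[f"m{j:04d}" for j in range(cfg.n_metabolites)],
                         columns=sess_ids)

    # ---- behaviour -------------------------------------------------------
    beh = {}
    for j in range(cfg.n_behavior):
        series = np.full(cfg.n_sessions, np.nan)
        vals = _tied_factor(f"behav:{j}", cfg, truth,
                            np.arange(cfg.n_sessions), rng)
        miss = rng.random(cfg.n_sessions) < cfg.missing_rate
        series[~miss] = vals[~miss]
        beh[f"behav:{j}"] = series
    beh["TuesThurs"] = truth.state_vector.astype(float)
    behavior = pd.DataFrame(beh, index=[f"ses{s:03d}" for s in range(cfg.n_sessions)])

    truth.gene_module_membership = membership
    truth.metab_cluster_membership = m_membership
    truth.gene_module_factors = factors
    truth.metab_cluster_factors = m_factors
    truth.omics_sessions = sess_idx
    return genes, metab, behavior


# ---------------------------------------------------------------------------
# TSV export

def write_dataset(outdir, sessions: list[SessionSeries], truth: GroundTruth,
                  genes: pd.DataFrame | None = None,
                  metab: pd.DataFrame | None = None,
                  behavior: pd.DataFrame | None = None) -> list[str]:
    """Write the generated dataset as TSV files plus a JSON ground truth."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    parcels = pd.DataFrame({
        "parcel_id": np.arange(truth.parcel_partition.size),
        "x": truth.centroids[:, 0], "y": truth.centroids[:, 1],
        "z": truth.centroids[:, 2],
        "hemisphere": truth.hemisphere_labels,
        "network": truth.parcel_partition,
    })
    parcels.to_csv(outdir / "parcels.tsv", sep="\t", index=False)
    written.append("parcels.tsv")

    rows = []
    for s in sessions:
        for t in range(s.data.shape[1]):
            rows.append((s.session_id, t, int(s.censor_mask[t])))
    pd.DataFrame(rows, columns=["session_id", "t", "usable"]).to_csv(
        outdir / "sessions.tsv", sep="\t", index=False)
    written.append("sessions.tsv")
    for s in sessions:
        fn = f"series_{s.session_id}.tsv"
        pd.DataFrame(s.data.T, columns=[f"p{i}" for i in s.parcel_ids]).to_csv(
            outdir / fn, sep="\t", index=False)
        written.append(fn)

    if genes is not None:
        genes.to_csv(outdir / "genes.tsv", sep="\t")
        written.append("genes.tsv")
        anno = pd.DataFrame({"gene_id": genes.index,
                             "is_small_rna": genes.attrs["small_rna"].astype(int).values})
        anno.to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False)
        written.append("gene_annotations.tsv")
    if metab is not None:
        metab.to_csv(outdir / "metabolites.tsv", sep="\t")
        written.append("metabolites.tsv")
    if behavior is not None:
        behavior.to_csv(outdir / "behavior.tsv", sep="\t")
        written.append("behavior.tsv")

    gt = {
        "parcel_partition": truth.parcel_partition.tolist(),
        "hemisphere_labels": truth.hemisphere_labels.tolist(),
        "state_vector": truth.state_vector.tolist(),
        "trend_design": truth.trend_design.tolist(),
        "planted_associations": [list(a) for a in truth.planted_associations],
        "gene_module_membership": (None if truth.gene_module_membership is None
                                   else truth.gene_module_membership.tolist()),
        "metab_cluster_membership": (None if truth.metab_cluster_membership is None
                                     else truth.metab_cluster_membership.tolist()),
        "filter_counts": truth.filter_counts,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    written.append("ground_truth.json")
    return written
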