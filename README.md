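# phenodyn

Statistical analysis of dense longitudinal single-subject phenotyping:
resting-state connectome estimation and graph cartography, longitudinal
trend and fed/fasted state testing with autoregressive errors,
cross-domain association scanning, gene coexpression and metabolite
module extraction, structure–function comparison, and phenome-wide
network construction — with a synthetic-data generator that plants known
ground truth for every stage.

## Who this is for

Studies that scan, draw blood from and survey the *same person* dozens of
times over months face a statistical regime most neuroimaging and omics
tooling ignores: ~50–100 sessions, strong session-to-session
autocorrelation, a weekday-locked fed/fasted factor, uneven missingness
across modalities, and tens of thousands of candidate variable pairs.
`phenodyn` packages the analysis path for this regime, exercised
end-to-end on synthetic data with planted effects so every stage's
operating characteristics (calibration, recovery, false-discovery control)
are testable.

## The core methods

**Parcellated connectomes.** For each session, the parcel × parcel matrix
of Pearson correlations over usable (uncensored) frames; L1-regularized
partial correlations from the graphical lasso, with the penalty found by
monotone bisection so the nonzero-edge density hits a target (7.5% by
convention); L2 (ridge) partial correlations at fixed λ = 10⁻⁴. Partial
correlations use ρᵢⱼ = −Ωᵢⱼ/√(Ωᵢᵢ Ωⱼⱼ) from the precision matrix Ω.

**Graph cartography.** Graphs binarized at 1–6% edge density (pairs of
parcels closer than 30 mm excluded), seeded Infomap communities, and a
consensus partition: per threshold, modules of ≤ 8 parcels dissolve; each
node keeps its label at the sparsest threshold where it is assigned;
labels surviving at only one threshold are removed. Signed–weighted
modularity Q\* = Q⁺ − (s⁻/(s⁺+s⁻))·Q⁻, global efficiency
E = mean over pairs of 1/d(i,j), participation coefficient
Pᵢ = 1 − Σₘ (kᵢₘ/kᵢ)², and provincial/connector hub classes
(within-module z > 1; split at P = 0.3).

**Regression with ARMA errors.** Session series are autocorrelated, so a
naive Pearson test is anticonservative (rejection > 0.10 at nominal 0.05
on AR(1) pairs). Each association is tested by GLS with ARMA(p, q)
errors: d ∈ {0, 1} from a KPSS pretest, (p, q) over the exhaustive
[0..3]² grid by corrected AIC, exact innovations-algorithm likelihoods,
and a t test on the whitened regression. Scans are controlled with
Benjamini–Hochberg FDR (q = 0.1) plus an |r| > 0.2 effect-size gate;
Bonferroni-corrected p values are reported for headline tables.

**Omics modules.** Median-of-ratios size factors; filtering to mean
normalized counts in [4, 10000] and removal of small RNAs; a closed-form
variance-stabilizing transform under a fitted dispersion–mean relation
α(μ) = a₁/μ + a₀; nuisance regression; biweight midcorrelation, soft
thresholding at the scale-free criterion, topological overlap,
average-linkage clustering and module eigengenes (per-module first
principal components). Metabolite peak heights are normalized per session
and clustered with affinity propagation.

**Replication power.** Sessions needed for 80% power to detect a
correlation of magnitude r, via the bias-corrected Fisher-z
approximation: effect atanh(r) + r/(2(n−1)), null critical correlation
from the t distribution at n − 2 df, variance 1/(n−3).

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from phenodyn import (SimConfig, gen_parcel_sessions, full_correlation,
                      mean_connectome, binarize_at_density, detect_communities,
                      consensus_partition, network_summaries,
                      state_effect_test, replication_power, signed_modularity)

cfg = SimConfig(n_parcels=630, n_networks=12, n_sessions=30,
                timepoints_per_session=300, state_effect_size=0.08, seed=7)
sessions, truth = gen_parcel_sessions(cfg)

mean_c = mean_connectome([full_correlation(s) for s in sessions])
assignments = {d: detect_communities(binarize_at_density(mean_c, d), seed=0)
               for d in (0.01, 0.02, 0.03)}
part = consensus_partition(assignments)
print(f"consensus modules: {part.n_modules}, ARI vs planted networks: "
      f"{adjusted_rand_score(truth.parcel_partition, part.assignment):.3f}")
print(f"signed modularity: {signed_modularity(mean_c, part):.3f}")

summ = network_summaries(sessions, part)
res = state_effect_test(summ.iloc[:, 0].values, truth.state_vector)
print(f"fasted-fed effect: coef={res.coef:.4f}, t={res.t:.2f}, p={res.p:.2g}")
print(f"sessions for 80% power at |r|=0.54: {replication_power(0.54)[1]}; "
      f"at |r|=0.38: {replication_power(0.38)[1]}")
```

prints

```
consensus modules: 10, ARI vs planted networks: 0.892
signed modularity: 0.180
fasted-fed effect: coef=0.0700, t=9.70, p=1.9e-10
sessions for 80% power at |r|=0.54: 24; at |r|=0.38: 51
```

The consensus partition recovers the planted 12-network structure
(adjusted Rand index 0.89; two small networks merge at these densities),
the fed/fasted contrast on within-network connectivity recovers the
planted +0.08 shift with the correct sign, and the power solver
reproduces the 24- and 51-session requirements for replicating
correlations of 0.54 and 0.38.

A full pipeline run (simulate → connectome → networks → dynamics →
associate → omics → integrate, with a results manifest) is available from
the command line:

```sh
phenodyn run-all --out results_dir --seed 1
phenodyn show-config           # all tunable parameters and defaults
```

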