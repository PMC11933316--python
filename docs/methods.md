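# Methods

## Count model and β-scores

Counts `K_ir` for guide *i* in sample *r* are negative binomial with mean
`μ_ir` and dispersion `α_i` under the `Var = μ + αμ²` parameterization
(this convention is used everywhere — simulator, dispersion estimator,
likelihood — so no conversion step exists to get wrong). The mean is
log-linear:

    log μ_ir = log s_r + log b_i + Σ_c D_rc β_gc

Each (condition, day) pair is its own design column, fitted jointly
against the shared Day-0 baseline samples, so `β_gc` is the gene's
log-scale abundance change from Day 0 in that arm at that day. The NB
log-pmf reduces continuously to Poisson as α → 0 (switch below α = 1e−12).

**Optimization.** For each gene, the likelihood over its guides is
maximized jointly in `(log b_i, β_gc)` by full Newton steps using the
observed information matrix (the β blocks are mutually orthogonal because
each sample belongs to at most one contrast), globalized with step
halving on the log-likelihood, ridge 1e−10 on the information solve, and
per-step component clip at ±5. Convergence: max parameter change < 1e−6,
cap 100 iterations (non-convergence is flagged and the last iterate
reported). The log-likelihood is jointly concave in these parameters, so
the optimum is global. Standard errors are square roots of the inverse
observed-information diagonal; Wald z = β/se is reported but plays no
role in hit calling (which is the σ rule below).

**Degenerate inputs.** Guides with zero total count are dropped from a
gene's fit; a gene with no usable guide is skipped with a warning. A
contrast in which every guide has zero reads has no finite MLE; β is
capped at ±10 (`BETA_BOUND`), which reads as "fully depleted/enriched"
and keeps downstream statistics finite. η = log μ is clipped at ±300
before exponentiation.

**Dispersion.** Per guide, method-of-moments `α̂ = (s² − m̄)/m̄²` on
size-factor-normalized counts within replicate groups (samples sharing
condition and day), pooled across groups by count-weighted average and
clipped to `[0.01, 10]`. With two replicates this is noisy per guide;
the clip floor plus the weak dependence of β̂ on α keep the estimates
serviceable (a fully null simulated screen yields gene-level z with mean
≈ 0.07 and SD ≈ 1.1). No trend-fitting or empirical-Bayes shrinkage is
attempted — deliberately simpler than DESeq-style machinery, and adequate
for a statistic whose calling rule is distribution-relative.

**Normalization.** Size factors are DESeq-style medians of ratios
computed on the non-targeting controls only: controls measure nothing but
depth, whereas total-count scaling would absorb genuine selection signal.
Controls with a zero count in any sample are excluded from the geometric
means (log 0 undefined); if all controls are excluded the estimator falls
back to all all-positive guides with a warning. Raw counts are never
overwritten; the likelihood consumes raw counts plus size factors.

**Cell-cycle rescaling** (`cellcycle_normalize`, opt-in): per contrast,
β and se are divided by the median |β| of a reference gene set (default:
all fitted genes). This equalizes the growth-driven spread of β across
sampling days so that scores are comparable between conditions. It is a
declared stand-in: the upstream tooling this step emulates does not
document its algorithm, and the default pipeline omits it because the
per-day σ rule is already scale-free within a day.

## Hit calling

Per replicate, `Δβ_g(t) = β_g(drug, t) − β_g(vehicle, t)`; replicates are
averaged before calling (per-replicate calling available via the API).
Per day, genes with Δβ strictly above `mean + kσ` or below `mean − kσ`
(default k = 2) are called +1/−1. σ uses the population denominator (n) —
immaterial at genome scale, fixed for determinism. A zero-σ day makes no
calls and warns.

A gene is a **high-fidelity hit** when it carries the same-direction call
on at least `min_days` (default 2) of the late days (default {6, 8, 10}).
A gene qualifying in both directions (possible only with ≥ 4 qualifying
days) is flagged `ambiguous` and excluded from both directions —
"consistent" means one direction; conflicts are reported, not resolved by
vote. Under a fully null simulated screen the per-day call rate is the
Gaussian tail mass 2Φ(−2) ≈ 4.55% while the high-fidelity rate is a few
tenths of a percent, because the filter demands direction-consistent
recurrence.

**Clustering.** High-fidelity trajectories (replicate-averaged Δβ over
the available days) are grouped by agglomerative clustering, Euclidean
distance, Ward linkage (scipy linkage, deterministic), tree cut at k = 6
by default. Clusters are relabelled 1..k by descending centroid value at
the final day so label 1 is always the most-enriched late trajectory.
Metric/linkage/k are conventions, not estimates.

## Tiling (domain-scanning) screens

Per-sgRNA **survival rate**: counts are depth-normalized to CPM (not
control-ratio normalized — the tiling statistic is defined against its
own NTC reference below), replicate-averaged per (condition, day), a
drug/vehicle ratio ρ is formed per guide with a +0.5 pseudocount on the
averaged CPM values (tiling libraries are tiny; zero counts would produce
undefined ratios), and S = ρ / mean(ρ over the non-targeting controls).
The NTC mean of S is therefore exactly 1 at every day, and S is exactly
invariant to rescaling any sample's depth. Default days {2, 4, 6}
matching the shorter tiling time course.

**Domain β**: targeting guides are regrouped by their domain label and
fitted through the identical gene-level machinery; positive-control and
non-targeting guides stay out of the domain groups.

## Simulator

The generator is the exact generative counterpart of the fitted model, so
parameter-recovery tests are well-posed:

* guide *i* of unit *g* has initial fraction `p_i(0)` (log-normal with SD
  `skew_sigma`, default 0.5, normalized to sum 1 — real libraries are
  skewed), efficiency `w_i ~ Beta(5, 1)` (most guides cut well, a tail
  does not), and evolves as
  `p_i(t) ∝ p_i(0)·exp[(g_g + 1[drug]·e_g)·w_i·t/τ]`, renormalized;
* `g_g ~ Normal(0, 0.1)` is condition-shared knockout fitness;
  `e_g ∈ {+E, 0, −E}` is the planted treatment interaction
  (default E = 1, 5% of genes per direction);
* `τ` (default 2.0 days) converts effect size to per-day log-growth; with
  E = 1 a full-efficiency resistance guide enriches e-fold every 2 days
  under drug, a strong but realistic effect over a 10-day course
  (~7 population doublings);
* counts are NB(depth·p_i(t), α_sim) via a Gamma–Poisson mixture (valid
  for non-integer 1/α; α_sim = 0 degenerates to Poisson), default depth
  1e6 ≈ 240× guide coverage, α_sim = 0.05;
* Day 0 is drawn once per replicate and shared between arms; every
  (replicate, condition, day) stream has its own `SeedSequence([seed, r,
  cond, day])`, so draws are reproducible independent of sampling order;
* non-targeting guides have g = e = w = 0; `SimTruth` records the unit
  effect table plus per-guide resolved (w, p0, g, e), which lets tiling
  screens plant per-domain effects through the same path.

Defaults mirror the targeted study design: 1000 genes × 4 guides + 100
NTCs at desk scale (the genome-wide original is ~19k genes), 2
replicates, days {0, 2, 4, 6, 8, 10}; the tiling default is 58
domain-annotated guides across five domains of one gene (N-terminal
flexible region, SWIRM, amine-oxidase N/C lobes, Tower) + 2
positive-control + 10 non-targeting guides, days {0, 2, 4, 6}.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: guide-specific off-target effects, copy-number
artifacts, cell-to-cell MOI variation beyond representation skew, PCR
jackpotting beyond NB overdispersion, day-to-day depth drift, and
correlated gene effects (each gene's effect is independent). Recovery
rates measured here are upper bounds relative to real screens.

## Numerical conventions

* Even-length medians are midpoints of the two central values.
* Strict inequalities at the σ thresholds ("higher/lower than" is strict).
* Population (n) denominator for σ; n−1 for the dispersion moments.
* All randomness flows through integer seeds; identical inputs give
  byte-identical outputs (tested).

## Known limitations

* β̂ for fully-depleted contrasts sits at the ±10 cap, a reporting
  convention rather than an estimate.
* The dispersion estimator is per-guide method-of-moments without
  shrinkage; with two replicates, individual α̂ values are noisy.
* The cell-cycle rescaling rule is a declared stand-in (see above).
* Hit calling is threshold-based by design; no FDR machinery, permutation
  p-values, or sgRNA-level rank aggregation is provided.
* The number of trajectory clusters (k = 6) and the Ward/Euclidean choice
  are conventions; silhouette-style model selection is out of scope.
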