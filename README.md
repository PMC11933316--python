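# screenpulse

Analysis toolkit for **temporally resolved pooled CRISPR knockout screens**
and **sgRNA tiling (domain-scanning) screens**, with a count-level screen
simulator that emits ground truth for validation.

The package targets the drug-modifier screen design: cells carrying a
genome-wide knockout library are split into vehicle (DMSO) and drug (e.g.
decitabine, "DAC") arms, sampled every other day out to Day 10 in two
replicates, and sequenced for sgRNA abundance. The goal is to identify
genes whose knockout changes drug sensitivity, and — in a follow-up tiling
screen — which protein domains of one hit gene carry that function.

## The model

sgRNA counts are modelled as negative binomial, `Var = μ + αμ²`, with a
log-linear mean per guide *i* and sample *r*:

```
log μ_ir = log s_r + log b_i + Σ_c D_rc β_gc
```

* `s_r` — per-sample size factor (median of ratios over non-targeting
  control guides against their geometric mean),
* `b_i` — per-guide baseline abundance,
* `D` — 0/1 design matrix with one column per (condition, day) contrast;
  shared Day-0 samples are the baseline (all-zero rows),
* `β_gc` — the gene's log-scale selection coefficient ("β-score"):
  positive = enrichment, negative = depletion relative to Day 0.

β is estimated per gene by joint Newton maximization of the NB likelihood
across the gene's guides; per-guide dispersions `α_i` come from
method-of-moments on replicate groups. Downstream:

1. **Differential β**: `Δβ_g(t) = β_g(drug, t) − β_g(vehicle, t)` per
   replicate, then replicate-averaged — isolates drug-specific selection
   from baseline knockout fitness.
2. **Per-day calling**: genes with `Δβ` strictly above `mean + 2σ`
   (positively selected — knockout confers drug resistance) or below
   `mean − 2σ` (negatively selected — knockout sensitizes) per day,
   with mean and σ taken over all genes of that day.
3. **High-fidelity filter**: same-direction calls on ≥ 2 of Days 6, 8, 10.
4. **Trajectory clustering**: Ward-linkage hierarchical clustering of the
   high-fidelity genes' Δβ time courses.

For tiling screens, each domain is treated as a "gene" for β fitting, and a
per-sgRNA **survival rate** is computed: CPM-normalized, replicate-averaged
drug/vehicle count ratios rescaled so the non-targeting-control mean is
exactly 1.

## Worked example

Simulate a 500-gene screen with 25 planted resistance genes (treatment
effect +1) and 25 sensitization genes (−1), then run the full chain:

```python
import screenpulse as sp

lib   = sp.make_library(n_genes=500, sgrnas_per_gene=4, n_ntc=50, seed=0)
truth = sp.draw_effects(lib, frac_resist=0.05, frac_sens=0.05,
                        effect_size=1.0, seed=0)
cfg   = sp.SimConfig(n_genes=500, n_ntc=50, depth_per_sample=500_000, seed=0)
cm    = sp.simulate_screen(lib, truth, cfg)

fits  = sp.fit_screen(cm, lib)                      # {replicate: BetaTable}
diffs = [sp.differential_beta_from_table(fits[r]) for r in fits]
avg   = sp.average_replicates(diffs)
ht    = sp.high_fidelity_hits(sp.select_hits(avg, k_sigma=2.0),
                              days=(6, 8, 10), min_days=2)
print(ht.thresholds.round(3))
```

```
      mean  sigma     lo     hi
day
2   -0.056  0.291 -0.638  0.525
4   -0.021  0.534 -1.090  1.048
6    0.006  0.784 -1.561  1.573
8    0.036  1.046 -2.056  2.127
10   0.065  1.379 -2.693  2.823
```

The per-day thresholds widen with time because selection (and hence the
spread of Δβ) accumulates. The filter recovers every planted gene here:

```
high-fidelity positive: 25  negative: 25
recall of planted resistance genes: 1.0
```

Clustering the 50 high-fidelity trajectories (`sp.cluster_trajectories(...,
k=4)`) separates steadily enriching resistance genes (cluster 1, Δβ rising
to +4.3 by Day 10) from progressively depleting sensitization genes
(clusters 2–4, falling to −3…−7), mirroring the "rapid and lasting" vs
"gradually dominating" trajectory classes such screens report.

The same stages are available from the shell:

```
screenpulse simulate --outdir sim/ --seed 0
screenpulse run --workflow genomewide --counts sim/counts.tsv \
    --library sim/library.csv --outdir results/
screenpulse run --workflow tiling --counts tiling/counts.tsv \
    --library tiling/library.csv --outdir results_tiling/
```

Outputs are plain TSV (`beta.tsv`, `diff.tsv`, `hits.tsv`,
`thresholds.tsv`, `clusters.tsv`, `surv.tsv`, `domain_beta.tsv`) plus a
`manifest.json` recording input hashes and parameters; reruns are
byte-identical. Exit codes: 0 ok, 2 config error, 3 data error, 4
numerical failure.

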