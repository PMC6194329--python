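# trophimix

Integrative diet analysis for predatory reef fish — for trophic
ecologists combining three complementary windows on a predator's diet:

1. **Visual stomach contents** — classic dietary indices (%N, %O, %W,
   %IRI = normalised (%N+%W)·%O) and prey accumulation curves for
   sampling adequacy;
2. **DNA metabarcoding of stomach contents** — quality filtering of
   BLAST-style hit tables (read share ≥ 0.1% of the stomach library,
   identity ≥ 98%, fragment length within 10% of the 313 bp COI
   amplicon) and collapse to per-stomach prey lists;
3. **Stable isotopes (δ13C, δ15N)** — SIAR-style Bayesian mixing models

   x_ij ~ Normal( Σ_k p_k(μ_jk+λ_jk), Σ_k p_k²(ω_jk²+τ_jk²) + σ_j² ),
   p ~ Dirichlet(α)

   with tissue discrimination factors (λ, τ), priors calibrated from
   DNA-identified stomach contents (α₀ solved so the largest component's
   prior SD equals a target SE, 0.078 by default), source-confounding
   diagnostics, and 75% credibility summaries.

Around these sit community statistics (Bray–Curtis, permutation ANOSIM,
simplified Morisita overlap with the 0.60 convention, nMDS), Jacobs'
electivity D = (r−p)/(r+p−2rp) with reef-replicate confidence intervals
and a ±0.25 neutrality band, and tissue-turnover temporal matching
(δ15N half-lives: plasma 66 d, RBC 88 d, muscle 126 d) that pairs each
tissue sample with the stomach-content sampling event it should
reflect. A synthetic-data generator with known ground truth makes every
stage testable end to end. See `docs/methods.md` for the full model
descriptions.

## Worked example

```python
import numpy as np
from trophimix import (default_scenario, synthetic, filter_hits, hits_to_prey,
                       calibrate_prior, MixingProblem, fit_mixing_model)

sc = default_scenario(seed=1)
records = synthetic.simulate_stomachs(sc, n_predators=120)
hits = synthetic.simulate_hit_table(records, sc)
kept, report = filter_hits(hits)
print(report["n_kept"], "of", report["n_input"], "hits kept")
dna_records, composition = hits_to_prey(kept)
print(composition.round(3))

prior = calibrate_prior(composition.reindex(sc.prey_categories, fill_value=0.0)
                        .pipe(lambda s: s / s.sum()).to_numpy())
consumers = synthetic.simulate_consumers(sc, "muscle", 40)
problem = MixingProblem(
    consumers=consumers[["d13C", "d15N"]].to_numpy(),
    source_names=sc.prey_categories,
    source_means=sc.source_means, source_sds=sc.source_sds,
    tdf_means=sc.tdf_means["muscle"], tdf_sds=sc.tdf_sds["muscle"],
    prior_alpha=prior.alpha,
)
summary = fit_mixing_model(problem, n_iter=10_000, n_chains=4, seed=1)
print(summary.to_frame().round(3))
```

prints

```
258 of 284 hits kept
prey_category
Pomacentridae          0.290
Caesionidae            0.266
Labridae               0.141
Labridae (Scarinae)    0.124
Serranidae             0.100
Acanthuridae           0.079
Name: proportion, dtype: float64
                      mean  ci_low  midvalue  ci_high   rhat      ess
Caesionidae          0.348   0.301     0.348    0.395  1.005  561.462
Pomacentridae        0.269   0.191     0.270    0.350  1.006  581.910
Labridae             0.139   0.083     0.141    0.199  1.015  520.248
Labridae (Scarinae)  0.075   0.041     0.075    0.109  1.005  557.476
Acanthuridae         0.055   0.022     0.057    0.092  1.010  559.791
Serranidae           0.113   0.064     0.113    0.161  1.012  445.767
```

The 26 rejected hits are the generator's planted contaminants (each
violates one filter rule). The DNA composition recovers the scenario's
true diet — Caesionidae + Pomacentridae jointly 0.65 true, 0.56 in the
(per-stomach-deduplicated) DNA diet — and the mixing posterior puts
those two planktivore families on top with 75% credibility intervals
covering the true proportions (0.35 and 0.30); R-hat ≤ 1.1 on every
source confirms the chains mixed.

The same workflow is laid out as narrative steps in `analysis/01…07`
(simulate → indices → filter → community stats → electivity → mixing →
temporal validation), each writing its tables under `results/`, and as
a CLI: `trophimix simulate|indices|filter-hits|anosim|electivity|mix|match|run`.

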