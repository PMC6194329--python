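# Methods

`trophimix` implements an integrative diet analysis for predatory reef
fish, combining visual stomach contents, DNA metabarcoding of stomach
contents, and stable-isotope mixing models. This note records the
models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Dietary indices (visual stomach contents)

For prey category *i*: %N_i = 100·n_i/Σn (item counts),
%O_i = 100·s_i/S where s_i is the number of stomachs containing
category *i* and S the number of stomachs with at least one
*identifiable* prey item (not all stomachs examined — empty and fully
digested stomachs are excluded from the occurrence base), and
%W_i = 100·w_i/Σw over wet weights. Only fresh items (digestion level
1–2) carry weights; weight is not corrected for partial digestion, so
%W and %IRI are biased low for quickly digested prey. The index of
relative importance is IRI_i = (%N_i + %W_i)·%O_i, reported as
%IRI_i = 100·IRI_i/ΣIRI. Categories are family-level; Labridae is
optionally split into Scarinae (herbivorous/detritivorous parrotfishes)
and all other, mostly predatory, labrids because the two feeding modes
occupy different trophic roles. Display tables are sorted by descending
%N with alphabetical tie-break and rounded to one decimal; full
precision is kept internally.

Sampling adequacy uses the random-order prey accumulation curve: the
mean over random stomach orderings of the cumulative number of distinct
families. The asymptote diagnostic is the least-squares slope of the
last 20% of the mean curve. Note the curve mean at k stomachs is
bounded by the total family count but *not* by k — a single stomach can
hold several families.

## Metabarcode hit filtering

A hit (one contig's taxonomic assignment in one stomach library) is
kept iff all three hold:

- read share: read_count / stomach-library total ≥ 0.1%;
- pairwise identity ≥ 98%;
- fragment length within ±10% of the expected 313 bp COI amplicon
  (real-valued window [281.7, 344.3]; integer lengths compared
  directly, so 282–344 bp pass).

The source criteria are stated as rejection conditions with strict
inequalities, so values exactly at a threshold are kept; thresholds are
configurable. The read-share denominator is the per-stomach library
total before filtering (the natural reading of "per sample" for
individually indexed stomach libraries). Kept hits are deduplicated at
species rank within each stomach — one prey item per distinct species
per stomach — then rolled up to family. Filtering is idempotent and
monotone in each threshold.

## Community statistics

Bray–Curtis dissimilarity d(x,y) = Σ|x−y|/Σ(x+y), binarised first for
presence/absence (the Sørensen complement). All-zero rows have
undefined dissimilarity to nonzero rows; those entries are set to 1 and
the rows flagged. ANOSIM follows Clarke's rank formulation with
mid-ranks for ties (vegan-compatible):
R = (mean between-group rank − mean within-group rank)/(M/2),
M = n(n−1)/2, and a label-permutation p-value
(#{R_perm ≥ R_obs}+1)/(n_perm+1) — the +1/+1 correction keeps p > 0.
999 permutations by default. Groups of size 1 are rejected (their
within-group ranks are undefined). An exhaustive-enumeration variant
(`anosim_exact`) serves as an oracle for small problems.

Niche overlap uses the simplified Morisita (Morisita–Horn) index
C = 2Σp_iq_i/(Σp_i² + Σq_i²) on normalised compositions, with overlap
above 0.60 flagged as significant by the usual convention. nMDS is
SMACOF stress majorization with monotone (isotonic) regression
(scikit-learn), best of several random starts, reporting Kruskal
stress-1. The embedding is a visualisation aid; its stress is
data-dependent and not a correctness surface.

## Electivity

Jacobs' D = (r − p)/(r + p − 2rp) with r the diet proportion and p the
environmental proportion; D ∈ [−1, +1], −1 maximum avoidance, +1
maximum preference, 0 proportional consumption. r = p returns exactly 0
(including the degenerate r = p = 1 corner); r = p = 0 is undefined and
returned as missing. One D per survey reef (pooled diet r against each
reef's availability) gives replicates for a 95% t-interval — a
t-interval was chosen because the reef replicates are few (typically
four); a bootstrap would be unstable at that n. Classification:
*neutral* if the CI lies inside (−0.25, +0.25); *preference*/*avoidance*
if the CI lies entirely above/below zero (and not inside the band);
*indeterminate* when the CI straddles a band edge, or fewer than two
reefs yield a defined D. Families absent from the surveys (never
counted on transects) cannot receive a D and are excluded with a note.

## Bayesian mixing model

The likelihood is the marginalised source-sampling model used by SIAR:
consumer i, isotope j ∈ {δ13C, δ15N},

x_ij ~ Normal( Σ_k p_k(μ_jk + λ_jk), Σ_k p_k²(ω_jk² + τ_jk²) + σ_j² )

with source means/SDs μ, ω; tissue discrimination factors λ, τ; diet
proportions p ~ Dirichlet(α); and per-isotope residual SD σ_j with a
half-Cauchy prior scaled to the observed isotope spread. Concentration
dependence and between-isotope correlation are omitted.

**Prior calibration.** Stomach-content information enters as a
Dirichlet prior: given the DNA-derived mean proportions m, the
concentration α₀ solves sqrt(m*(1−m*)/(α₀+1)) = SE for the
largest-mean component m* and a target prior standard error (0.078 by
default, deliberately conservative so the stomach data guide rather
than dominate the model); α = α₀·m, floored at 0.01 per component.
Which component an SE target should pin is genuinely ambiguous; the
largest-mean component was chosen because it is the best-estimated one
in stomach data. Without stomach data the prior is flat, Dirichlet(1).

**Sampling.** Random-walk Metropolis on the additive-log-ratio
transform of p jointly with log σ. In ALR space the Dirichlet prior
plus Jacobian reduce to Σ_k α_k log p_k, and the Gaussian likelihood
needs only the per-isotope sufficient statistics Σx and Σx², so chains
are cheap and run vectorised. The per-chain proposal scale adapts every
50 burn-in iterations toward ~30% acceptance (kept within the 20–40%
band appropriate for multivariate RW proposals); once enough burn-in
history accumulates, the proposal covariance is re-estimated from the
chain history every 200 burn-in iterations (Haario-style adaptive
Metropolis, initial scale 2.38/√d) — this matters when sources are
isotopically close and the posterior is strongly correlated. Scale and
shape are frozen after burn-in. Defaults: 4 chains × 10 000 iterations,
first half burn-in,
overdispersed N(0,1) starts in ALR space. Convergence: split R-hat and
a Geyer initial-positive-sequence effective sample size per source; any
R-hat > 1.1 flags the summary as non-converged (returned with a
warning, never silently accepted). Credibility intervals are
equal-tailed quantile intervals, 75% by default; the midvalue is the CI
midpoint.

**Confounding.** Sources with similar corrected signatures produce
strongly negatively correlated posterior contributions. Pairs with
posterior correlation ≤ −0.7 are flagged (the threshold is this
package's choice; diagnostic plots alone give none). Flagged sources
can be merged: the combined mean is the prior-weighted member mean, the
combined variance is the weighted within- plus between-member variance,
and prior alphas add, conserving total concentration.

**With/without-prior comparison** uses the simplified Morisita index on
the renormalised 75%-CI midvalue vectors, 0.60 significance convention.

## Turnover and temporal matching

δ15N half-lives: plasma 66 d, RBC 88 d, muscle 126 d; the same values
are used for δ13C because tissue-specific carbon turnover estimates are
not available for this system. A tissue sampled at date T is compared
with stomach contents sampled near T − half-life; matching is greedy
nearest-lag within a ±45-day default tolerance (sampling campaigns are
months apart; note a ~180-day muscle-to-stomach pairing needs the
tolerance widened to ~60 d), same group and reef required, ties to the
earlier stomach event, and one stomach event may serve several tissue
events. Validation reports, per prey category, whether the DNA
proportion lies inside the posterior 75% CI, plus the Morisita overlap
of the CI midvalues against the DNA composition. Incorporation is
gradual, so these windows are approximate by construction; no
continuous-time turnover curve is modelled.

## Synthetic data: what it emulates and what it does not

The generator draws, per predator group: empty stomachs with a set
probability (default 0.56, i.e. 44% of stomachs contain prey);
zero-truncated Poisson item counts per non-empty stomach (mean 2.5 —
the item-count law is not identified by occupancy data alone, so this
is a stand-in; a per-category digestion distribution can be supplied to
break the default taxon-independence of digestion level); multinomial
taxa from the group's true diet. Hit tables give true prey identities
≥ 98%, in-window lengths, and comfortable read shares, while
contaminants (10% of rows in expectation) each violate exactly one
filter rule, so filter sensitivity/specificity are exactly computable —
real contamination is not guaranteed separable, so perfect confusion
scores say the rules are implemented correctly, not that 98%/0.1%/±10%
are optimal for real libraries. Consumers follow exactly the mixing
model's marginal likelihood, so parameter-recovery tests check the
sampler and model code, not robustness to model misspecification (real
tissues violate the model through isotopic routing, unsampled sources,
and temporal averaging). Surveys are multinomial around per-reef
availability. Default isotope geometry spans δ13C −19 to −12 ‰ and
δ15N 7 to 12 ‰ with 0.5 ‰ within-family SD and 0.3 ‰ residual —
realistic for reef fish families — which leaves some families
isotopically close on purpose: the confounding diagnostic has something
real to find (planktivores Caesionidae/Pomacentridae flag reliably).

Each generator operation draws from its own RNG stream
(`scenario.seed` + a fixed per-operation offset), so tables are
byte-identical for a given scenario regardless of call order.

## Problem sizes

Default analysis/test sizes were chosen so statistical checks are
well-powered while the whole suite stays quick: 120 predators per group
for compositions, 40–50 consumers per mixing fit, 4 chains × 10 000
iterations (recovery studies over 50 seeds), ANOSIM calibration with
500 null replicates × 199 permutations, end-to-end consistency over 20
seeds at 8 000 iterations.

## Known limitations

- The published visual-contents table's %IRI row is not reproducible
  from its printed %N/%O/%W marginals under IRI = (%N+%W)·%O (nor under
  the Pinkas %N·%W form); the %N and %O rows reproduce exactly from
  integer count bases, and %IRI is computed only from raw records.
- The typeset Jacobs formula in the source literature description is
  corrupted ("D = r − p/(r + p) − (2rp)"); the standard Jacobs (1974)
  form is implemented, and "varies from 1 (maximum avoidance)" is read
  as −1.
- ANOSIM permutation count (999) and the confounding threshold (−0.7)
  are conventional choices, not estimated quantities.
- The SE-calibrated Dirichlet prior is one defensible operationalisation
  of "a standard-error target for stomach-content priors"; pinning a
  different component, or all components, would give different α₀.
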