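# Methods

`secboost` identifies genetic variants with shared causal effects across
multiple traits — molecular QTLs, or molecular QTLs together with a
disease GWAS — by multi-task gradient boosting with *single-effect
coupler* (SEC) weak learners, and summarizes the evidence as
colocalization confidence sets (CoS) and per-variant colocalization
probabilities (VCP).

## Model

For traits l = 1, …, L with standardized phenotypes Y_l ∈ ℝ^{N_l} and
column-standardized genotype matrices X_l ∈ ℝ^{N_l×P}, each trait follows
the linear model Y_l ~ N(X_l β_l, σ_l² I).  The joint objective is the sum
of squared-error losses, 𝓛(β_1,…,β_L) = Σ_l ‖Y_l − X_l β_l‖².  All
likelihood statements use the *profile* log-likelihood −(N/2)·log(RSS/N)
(residual variance profiled out), so every quantity in the algorithm is a
function of the moments X^T r, ‖r‖² and N.  That has a practical
consequence: the engine runs identically on individual-level data and on
summary statistics, because z-scores plus an LD panel determine exactly
those moments (`sumstats.sufficient_stats` uses the exact t-statistic
back-transform ρ = z/√(z² + N − 2), so toy sample sizes round-trip without
large-N error).

## The proximity-smoothed weak learner

Updating only the best single-effect variant j* = argmax_j |X_j^T r| is
unreliable under linkage disequilibrium.  Each update is therefore a
distribution over the LD proximity of j*:

* local association simplex δ_j ∝ exp(LD(j, j*) · h(z_j)), with
  h(z) = (1−λ)|z| + (λ/2)z² an elastic-net shaped score of the residual
  association z-score (λ = 0.5);
* smoothed weights ξ_j ∝ δ_j · exp(|g_j|/τ) normalized to sum 1/(N−1),
  where g_j = X_j^T r/(N−1) and τ = 0.01 is the softmax temperature;
* residual step r ← r − η·d along d = Σ_j ξ_j·sgn(X_j^T r)·X_j, with
  η = κ·(d^T r)/(d^T d) a shrunken exact line search (κ = 0.3).  Every
  accepted step strictly reduces the residual sum of squares, and the
  per-round profile log-likelihood gain Δ𝓛 is recorded.

Two numerical guards matter in practice.  All softmaxes subtract the max
exponent (|g|/τ reaches several hundred at τ = 0.01).  And the ξ support
is restricted to |LD(j, j*)| ≥ 0.2 (`prox_min`): without the restriction
the |g|/τ term (≈3z on standardized data) can overwhelm the δ prior
(≈h(z)) when a trait carries a second, partially fitted signal elsewhere,
leaking one round's mass across two unrelated effects and corrupting the
downstream clustering.  The smoothed update is by construction a
distribution over the anchor's proximity; the support restriction makes
that explicit.

## Coupling updates across traits

Each round picks the cross-trait best variant j* (argmax of the
l1-aggregated absolute gradients) and checks, per trait, whether the
trait's own best j_l is *equivalent* to j*: the variants coincide or are
tight LD proxies (|r| > 0.8), and the trait's profile log-likelihood drop
at the two variants is comparable (relative gap < ε = 0.1).  The
scheduling decision tree:

* **Logic 1** — all traits equivalent: one coupled update at j*, with
  trait-specific proximity smoothing.
* **Logic 2** — no trait equivalent: partition traits into pairwise
  equivalence groups; couple the group with the largest Δloglik at its own
  recomputed best (2.1), else update each singleton trait at its own best
  (2.2).
* **Logic 3 (delayed SEC)** — a proper subset equivalent: if the coupled
  subset's weakest Δloglik at j* still beats the best trait-specific
  signal outside it, couple at j* (traits outside join when their Δloglik
  at j* reaches 50% of their own best *and* their z at j* is single-test
  significant); otherwise defer j* and serve the outside traits first.
  Deferral prevents LD-induced horizontal pleiotropy: a trait whose
  stronger private effect merely tags j* would otherwise be coupled
  prematurely.

**Disease-prioritized mode (E-SEC).**  With a focal trait (typically a
GWAS), a pre-step replaces the candidate variant of the round with the
aggregate best over the focal trait's equivalence group — the traits
whose own best variants are equivalent to the focal trait's peak — while
any such trait exists (retired after 3 consecutive empty rounds, or when
the focal trait converges).  Which traits actually update there is still
decided by the dynamic coupling logic, so delayed-SEC protection stays in
force; the focal trait itself joins the update by *corroboration* — the
independent agreement of the other traits' peaks with its own — with no
evidence bar on its own z-score.  That admission rule is the operational
meaning of prioritization, and its cost is known: a focal trait with no
true effect is spuriously coupled when its noise peak happens to fall in
a molecular signal's LD clique, roughly once per (number of LD blocks)
per signal, which is why the disease-prioritized mode trades a small
amount of FDR for focal-trait power.

**Trait gate, passive joins, and termination.**  A trait enters the loop
only if its strongest marginal association clears a Bonferroni bound
α/P (α = 0.05, two-sided); greedy boosting on pure noise does not
terminate and is the chief Type-I-error risk, so traits without
locus-wide-significant evidence never drive updates.  Once a fitted
trait's residual peak falls back below that bound it stops driving the
scheduler and enters a *finishing* phase: it keeps updating within tight
LD (≥ 0.8) of its already-committed anchors until the window criterion
fires (relative SSE improvement over 5 consecutive updates < 1e-4).
Finishing matters twice over: signals are fitted to completion rather
than ~70% (whence stable per-event likelihood contributions), and no
above-noise leftovers remain to spawn duplicate anchors at moderate
proxies.  Separately, a trait that no longer drives scheduling can still
*passively join* an update at an anchor chosen by the other traits when
its own |z| at that single pre-chosen variant is significant at
p < 1e-3 — a single test, since the anchor selection paid the locus-wide
multiplicity.  Joining the strongest eligible anchor takes priority over
a finishing self-update (the polish round can wait), and finishing
traits may join each other's anchors.  Passive joining is how a weak
trait (e.g. a GWAS with per-variant heritability ~2%) borrows strength
from stronger molecular traits.  The loop ends when every trait is
converged, or at `max_rounds` = 500.

## From rounds to colocalization events

Weak learners deliberately spread one causal effect over many rounds and
nearby anchors, so rounds are clustered before inference.  Nodes are
single-effect units (round × anchor; a trait-specific round updating
several traits at different anchors contributes one node per anchor).
Edge weights are cosine similarities of the units' weight vectors,
averaged over shared traits, computed in the |LD| bilinear metric
(x^T|R|y, normalized): near-one-hot vectors on tight proxies of one
effect are then similar, while vectors on uncorrelated variants (distinct
effects) are not.  Edges below 0.5 are dropped, communities come from
greedy modularity maximization (networkx), and units sharing an anchor
always co-cluster.

Within a cluster s, per-trait variant weights are the gain-weighted
averages W_jls = Σ_k Δ𝓛_k ξ_jlk / Σ_k Δ𝓛_k, and traits are combined as
W_js = (Π_{l∈T_s} W_jls)^{v/|T_s|} with v = 1.5, keeping the scale
comparable across configuration sizes.  The 95% CoS is the smallest
weight-ordered set of variants whose normalized W_js reaches the coverage
level (ties to the lower index).  Filters then drop:

* trait memberships contributing < 2.5% of that trait's total boosting
  gain, or < 10% of the trait's strongest event;
* events with purity (minimum pairwise |LD| inside the CoS) below 0.5;
* events left with fewer than two traits (unless they contain the focal
  trait in disease-prioritized mode).

Events whose CoS overlap heavily (Jaccard > 0.5) *or* whose lead variants
are tight LD proxies (|r| > 0.8) are merged — two compact descriptions of
one effect can share no variants at all, so the lead-proxy clause is
essential.  Finally VCP_j = 1 − Π_s(1 − W_js), and MaxVCP is the maximum
VCP across genes for a variant appearing in several cis windows.

## Summary statistics, trait-specific LD, LD-free mode

Traits are harmonized onto the union variant universe without imputation;
a variant absent from a trait contributes zero gradient there.  Variants
missing from a trait's LD panel are retained but flagged: they never
serve as anchors and receive proximity mass only through observed pairs.
Each trait may use its own LD panel; cross-trait variant comparisons use
the largest |LD| any panel supplies.  Without any panel, the LD-free mode
assumes a single causal variant per signal: δ degenerates to the anchor,
updates are pure coordinate steps, coupling requires exact peak
coincidence, and at most one event is reported per trait configuration.

## The synthetic-locus generator

The generator reproduces the statistical structure of a cis locus rather
than any particular cohort:

* **Genotypes** — latent-Gaussian copula, AR(1) within blocks (block size
  10; ρ ~ U(0.6, 0.95) per block), independent across blocks; two latent
  haplotypes thresholded at MAF ~ U(0.05, 0.5) give dosages in {0, 1, 2}.
  This produces the two LD regimes the algorithm must face — tight
  proxies within blocks, independence across — but not real-data features
  like long-range LD gradients, allele-frequency/LD coupling, or
  population structure, so passing tests certify calibration under clean
  block LD, not robustness to reference mismatch.
* **Causal architecture** — 1–5 causal variants, re-drawn until pairwise
  |LD| < 0.3; each causal variant's trait configuration size is drawn
  from the empirical distribution (2:38.0%, 3:28.5%, 4:16.3%, 5:7.9%,
  6:5.1%, 7:2.4%, 8:1.2%, 9:0.4%, 10:0.2%), truncated and renormalized
  for L < 10; members are a uniform subset (always including the focal
  trait in the disease-prioritized design; with L = 2, both traits share
  every causal variant).
* **Traits** — Y = Xβ + ε with |β_j| solved by fixed-point iteration so
  each causal variant explains exactly φ of the trait variance
  (xQTL default φ = 0.05; disease-like traits use φ in 0.02–0.04);
  signs ±1 equiprobable; residuals independent across traits by default,
  or exchangeable-correlation ρ = 0.3 jointly Gaussian on request.
  The null model sets every β = 0 and draws σ_y² ~ U(0.1, 1) per trait.

Everything is reproducible from (parameters, seed).

## Evaluation statistics

Power and FDR are scored at the level of whole configurations: an event
earns credit for causal variant j only if its CoS contains j and its
trait set is a subset of j's true trait set (credit = correctly assigned
traits; power = total credit / total true trait assignments), and an
event is a false discovery if it misses every causal variant or assigns
any extra trait.  Variant-level ranking uses precision-recall of VCP with
step-wise (no linear interpolation) area.  Gene-level metrics for
focal-trait benchmarks merge nested configurations and ask whether any
merged detected configuration contains the focal trait.  The
excess-of-overlap statistic EOO = (|VG1∩VG2|/T12)/((|VG1|/T1)(|VG2|/T2))
equals 1 exactly at independence; its standard error is a delete-one
jackknife over user-supplied blocks.

## Problem sizes used for verification

The acceptance script runs the primary experiment at 200 loci per
scenario over {2, 5, 10} traits × {1, 3, 5} causal variants with
N = 1,100 and P = 1,000, plus 400 null loci (2–10 traits); the test suite
re-runs the same designs at 15 loci per scenario and P = 500, 200 null
loci at P = 400, 300 single-causal loci for CoS coverage, and 200
replicates for the disease-prioritized comparison.  These sizes are the
package's verification scale; all scenario parameters (φ, N, the
configuration table, LD regime) are the study conditions themselves and
are never adjusted per experiment.

## Known limitations

* The dynamic learning rate is a shrunken exact line search; the original
  procedure it stands in for is more finely adaptive, and our κ = 0.3
  fits a signal in ~10–25 rounds rather than hundreds, making per-round
  weight vectors more concentrated and the resulting CoS compact (often
  a single variant at N ≈ 1,000, φ = 0.05 under block LD).
* Cross-trait residual correlation is not modeled inside the coupler;
  the generator can produce it, and calibration under strong sample
  overlap should be checked before trusting events from heavily
  overlapping cohorts.
* The trait gate assumes the locus contains, at most, signals detectable
  at the Bonferroni bound α/P; a colocalization carried by traits all of
  which are individually sub-threshold is invisible by design (the
  passive-join path requires at least one gated-in trait to anchor).
* LD-free mode requires exact peak coincidence and loses power relative
  to the LD-aware mode whenever the top marginal hit is a proxy.
* No allele harmonization: inputs are assumed strand- and
  allele-consistent across traits and panels.
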