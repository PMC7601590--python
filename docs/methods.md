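# Methods

`rumenet` re-implements, as a tested library, the statistical workflow used
to relate anaerobic rumen fungi (Neocallimastigomycota, profiled by ITS1
amplicons) to rumen bacteria (16S V3–V4) in steers moving from an
alfalfa-hay baseline through a 3×3 crossover of alfalfa-pasture treatments
(pure alfalfa, PA; alfalfa + Alfasure pluronic detergent, AA; alfalfa +
sainfoin, AS), with frothy-bloat status recorded per grazing occasion.
The pipeline starts from ASV count tables — read processing and taxonomy
assignment are out of scope — and covers compositional preprocessing,
alpha diversity, constrained ordination, ensemble cross-kingdom
co-occurrence inference, and per-ASV differential abundance.

## Compositional preprocessing

Counts are compositional: only relative information survives sequencing.
The preprocessing chain is

1. **Taxonomy filter** — fungal tables are restricted to lineages
   containing `Neocallimastigomycota` (case-sensitive rank-token match).
2. **Rarefaction** — multivariate-hypergeometric subsampling without
   replacement to a fixed depth per kingdom (defaults 7 000 fungal,
   25 000 bacterial reads per sample, the depths used for the original
   libraries). Samples under the target are dropped with a logged
   warning; retaining them unrarefied would bias richness comparisons.
3. **Prevalence filter** — a taxon is kept when present (count > 0) in at
   least `ceil(f·n)` samples; `f = 0.50` feeds the ordination/network
   stages, `f = 0.10` the differential-abundance scan. The filter is
   applied after rarefaction (the order is a package choice; the
   alternative ordering changes little on data this dense).
4. **Zero replacement** — Bayesian-multiplicative imputation: in sample
   *j* with total *n_j*, a zero for taxon *i* becomes
   `t_i·s/(n_j+s)` with prior strength `s = 1` (configurable) and prior
   `t_i` the taxon's mean relative abundance where present; observed
   proportions are rescaled by `1 − Σ imputed`, preserving their ratios.
   An imputed value reaching the sample's smallest observed proportion is
   shrunk by 0.65 with a warning (with `s = 1` this cannot trigger, since
   `t·1/(n+1) < 1/n`; it guards larger priors).
5. **CLR** — `ln x_i − mean(ln x)` per sample; rows sum to zero and the
   transform is invariant to per-sample count scaling.

## Diversity

Chao1 (`S_obs + F1²/2F2`, bias-corrected `S_obs + F1(F1−1)/2` when no
doubletons) and Shannon entropy (natural log) are computed on rarefied
counts. Baseline-vs-treatment contrasts pair each steer with itself and
use a Wilcoxon signed-rank test whose null is evaluated **exactly** for up
to 25 effective pairs by dynamic programming over doubled midranks — ties
are common in matched sparse counts and scipy's exact path does not
handle them — and by a tie-corrected normal approximation beyond.
Fungal-vs-bacterial diversity association uses Spearman's rho (midrank
Pearson; exact permutation p for n ≤ 9, t approximation above).

## Ordination

RDA regresses the CLR matrix on a dummy-coded constraint;
`R² = SS_fit/SS_total`, `R²_adj = 1 − (1−R²)(n−1)/(n−1−p)`, and the
permutation p-value shuffles response rows (B = 999 by default,
`p = (1+#{F* ≥ F})/(B+1)`). Partial RDA residualizes both response and
constraint on the conditioning design and permutes reduced-model
residuals (Freedman–Lane). PERMANOVA partitions squared Bray–Curtis
distances (`SS_total = Σ_{i<j} d²/n`, within-group analogues divided by
group size) and permutes group labels; pairwise treatment contrasts run
as two-group PERMANOVAs on sample subsets. Matched-steer structure does
not restrict permutations by default; within-steer restriction is
available where the design warrants it.

## Ensemble co-occurrence network

Candidate edges are inter-kingdom pairs (fungus × bacterium) among taxa
passing the 50 % prevalence filter; each kingdom is closed to one and the
two blocks re-closed jointly so per-sample compositions sum to one.
Four measures score every pair: Spearman rho and Kendall tau-b (midranks
/ tau-b tie correction), Bray–Curtis dissimilarity across samples, and
symmetrized Kullback–Leibler divergence between across-sample profiles
(pseudocount 10⁻⁶).

* **ReBoot null** — per pair and measure, the two taxa are shuffled
  across samples independently (B_perm = 1000 by default; 200 in the
  scaled tests); for Spearman the shuffled values are put back into each
  sample's composition, which is re-closed before scoring, so that the
  null absorbs the association the pair's own closure induces. The
  dissimilarity measures and Kendall shuffle the pair alignment directly
  (configurable; a single relative permutation, distribution-identical to
  two independent shuffles for alignment statistics). The permutation
  engine is vectorized over permutations and pairs; tau-b tie terms are
  permutation-invariant, so only concordance counts are resampled.
* **Bootstrap** — samples are resampled with replacement (B_boot = 1000
  default) and all pair scores recomputed on the resampled table; the
  percentile 95 % interval and moments summarise each pair's stability.
* **Measure p-value** — `z = (null_mean − boot_mean)/boot_sd`, two-sided
  Gaussian tail. Direction is the sign of the observed correlation, or
  observed-vs-null for dissimilarities (greater than expected ⇒ mutual
  exclusion).
* **Merging and retention** — measures are partitioned by direction;
  support is the majority-direction count (ties broken toward the larger
  summed −ln p). Supporting p-values are merged by Brown's method with
  the covariance of the −2 ln p statistics estimated empirically across
  all candidate pairs and clipped to [0, 4]; Benjamini–Hochberg runs
  across pairs. An edge is retained when support ≥ 3, q < 0.05, and each
  supporting observed score lies inside its bootstrap CI.
* **Hubs** — top-4 nodes by degree per network (overall, bloat,
  no-bloat; strata contain grazing samples only), with boundary ties
  included and reported; the de-duplicated union feeds a partial RDA of
  the bacterial CLR matrix on hub-fungus CLR abundances conditioned on
  treatment and bloat status.

## Differential abundance

Each taxon's CLR abundance is tested against the diet/bloat-status
combination with an F statistic from the additive group + steer-block
fit; the null permutes group labels **within** steers (B = 4999 default,
199 in tests; exhaustive enumeration for small designs), realising
"steer as a random factor" permutation-exactly without a
variance-component fit. BH correction runs across taxa; flagged taxa get
matched-pairs Wilcoxon contrasts against baseline, and a Mann–Whitney
rank-sum for bloat vs no-bloat within AS (those groups contain disjoint
steers, so pairing is impossible), BH-corrected within each contrast.

## Synthetic data generator

The generator defines the conditions every statistical claim is tested
under. Twelve steers contribute one baseline sample and one sample per
crossover period (Latin-square treatment sequences); four grazing samples
(1 PA, 2 AA, 1 AS) are removed to reproduce the study's n = 44
(12/11/10/11). Bloat labels follow the study pattern (PA bloats, AA does
not, AS splits ≈ 6:5). Per-sample latent log-abundance of taxon *t* is

    base_t + treatment_shift(t, diet) + steer_effect + Σ_k L_tk f_ks + ε

with counts drawn multinomially from the per-kingdom softmax at a
lognormal per-sample depth matching the reported ITS/16S library sizes
(≈1.1×10⁵ ± 6.5×10⁴ and ≈5.6×10⁴ ± 1.9×10⁴), so rarefaction occasionally
drops a shallow sample, as in real data. Defaults: 30 target fungal taxa
(+6 off-target Ascomycota/Basidiomycota that exercise the phylum filter),
120 bacterial taxa, `base_sd = 1.5`, `steer_sd = noise_sd = 0.3`,
structural-zero probability 0.05, 30 % of taxa diet-responsive with
shared alfalfa shifts (SD 1.0) plus treatment-specific deviations
(SD 0.3).

Planted cross-kingdom structure uses **one standard-normal factor per hub
fungus**, loading +c on the hub and sign·c on each of its bacterial
partners (defaults: 5 hubs × 8 partners, c = 1.5, 80 % negative — the
mutual-exclusion-dominated pattern the analysis is designed to detect).
The shared factor is a deliberate choice: if each hub–partner pair had an
independent factor, positive-semidefiniteness would cap every hub–partner
correlation at `1/√(partners_per_hub)` ≈ 0.35 — a hub strongly associated
with eight mutually independent partners is mathematically impossible —
and no pair-level screen could recover the structure at n ≈ 44. Planted
taxa take baselines from the community's moderately abundant range
(N(0.5, 0.5)), mirroring that observed hub fungi are abundant community
members. `null_dataset` zeroes couplings and treatment effects and is the
type-I harness.

### What the generator does and does not emulate

It reproduces the crossover design, matched-steer dependence,
compositional sparse counts with realistic depth variation, separate
ITS/16S libraries, diet-driven community shifts and signed cross-kingdom
couplings. It does not emulate taxonomy-assignment error, phylogenetic
correlation among taxa, overdispersion beyond the logistic-normal layer,
or time trends within periods — so green tests certify the statistical
machinery under the stated model, not performance on arbitrary real data.

### Known limitation: indirect compositional associations

The same PSD argument above has a flip side: strong hub–partner
correlations force the partners of one hub to co-move
(`rho_pp ≥ (8·rho_hp² − 1)/7`). After closure, that co-movement makes
*every* taxon's relative abundance depend on the hub factors, creating
genuine indirect associations (|rho| ≈ 0.35–0.65, predominantly
co-presence: when a hub's mostly-negative partners fall, every other
bacterial fraction rises). ReBoot's renormalization discounts the
association a pair's *own* closure induces, not third-party effects, so
at the scaled test settings the ensemble recovers planted edges with
sensitivity ≈ 0.85 and finds all planted hubs, but planted-edge
precision plateaus near 0.75 and the recovered exclusion fraction sits
below the planted 0.8 because indirect co-presence edges are real
features of the relative-abundance data. Distinguishing direct from
induced association would require conditional (partial-correlation
style) inference, which is outside this package's scope; the recovery
tests assert the stricter targets and report the shortfall rather than
masking it.

## Numerical choices

Permutation p-values use the `(1 + #exceed)/(B + 1)` convention with a
10⁻¹² slack on F-comparisons; p-values are floored at 10⁻³⁰⁰ before
logs; Brown covariance terms are clipped to [0, 4]; degenerate
(zero-variance) vectors yield NaN scores and the measure is dropped for
that pair; rarefaction, the generator, and every permutation engine take
explicit seeds and never touch global random state (the pipeline derives
per-stage seeds from one master seed). The scaled problem sizes used
throughout the test-suite experiments (30×120 taxa, 44 samples,
B_perm = B_boot = 200, 5 seeds) are the package's standard evaluation
conditions; module defaults keep the full B = 1000 resampling of the
original analysis.
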