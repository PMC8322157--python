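# Methods

## The analysis unit: cytosine-cluster regions

Methylation in plants occurs in CG, CHG and CHH contexts (H ∈ {A, C, T}),
each maintained by a different pathway.  Rather than fixed-width windows,
the analysis unit is a *cluster of context cytosines*: CG and CHG sites
come in strand pairs (a CG dyad spans 2 bp; a CHG triad 3 bp — only the
palindromic CWG motif pairs, a CCG cytosine seeds alone because its
opposite-strand C is in CG context), CHH sites are strand-asymmetric and
seed individually.  Clusters are merged in rounds of increasing gap
distance d (gap = bases strictly between spans): at each d, a
left-to-right pass merges every adjacent pair with gap ≤ d whose merged
span stays within the cap, and a freshly merged cluster keeps extending
rightward while admissible.  This is equivalent to repeatedly merging the
globally closest admissible pair (leftmost on ties), which the test suite
verifies against a brute-force implementation on random genomes.

The 185 bp span cap corresponds to the abrupt drop in methylation
autocorrelation at about one nucleosome-plus-linker; the
`autocorrelation` operation recomputes that profile from per-cytosine
levels (Pearson correlation of all same-chromosome pairs at exact bp
distances, strands pooled, entries undefined below two pairs or at zero
variance).  Genome binning at 100 bp (trailing partial bin kept) is the
conventional baseline.

Coordinates are 0-based half-open internally; the count-table and GFF3
dialects are converted at the file boundary.  Organellar sequences can be
excluded with the pipeline's chromosome whitelist.

## Status calling

Counts are summed over each region's member cytosines, both strands.  Two
filters gate the analysis, both across *every* sequenced plant of a
pedigree: mean coverage strictly greater than 3 reads per cytosine
(total reads / member cytosines), and a maximum posterior ≥ 0.99.

Classification uses a 3-component binomial mixture over region counts,
fitted per context by EM (initial success probabilities 0.01 / 0.5 / 0.95,
equal weights; converged at < 1e-8 log-likelihood gain or 500 iterations;
components relabelled by ascending success probability; a collapsing
component falls back to the initialisation with a warning).  The posterior
over {U, I, M} is proportional to weight × binomial pmf; argmax ties break
toward I, the conservative middle class.  A region-level mixture was chosen
over a positional HMM deliberately: when the unit of analysis is a whole
region there is no positional sequence left for transitions to model, so an
emission-driven maximum-posterior classifier plays the identical role and
is directly testable against simulated counts.

## Pedigree and divergence

An MA pedigree is a tree of single-seed-descent selfing events: one
generation per edge, the line propagated through one sibling while another
is sequenced.  Δt between two sequenced plants is the edge count through
their most recent common ancestor; fitting uses the two branch lengths
(t_i, t_j) separately since expected divergence depends on both.

Pairwise divergence weights per region are 1 for {M, U}, 0.5 when exactly
one call is I, and 0 otherwise — half the L1 distance between states coded
0/1/2, hence a metric; D_ij is their mean over retained regions.  All
C(k, 2) sequenced pairs enter the fit.  The Fig.-4-style summary counts
regions whose calls include both U and M along a time-ordered branch, and
the fraction that never revert to the original pole in later sampled
generations (intermediate calls are ignored for stability, and a window of
"all subsequent sampled generations" is used).

## Inheritance model and rate estimation

Each region carries two epialleles; the epigenotype k ∈ {0, 1, 2} counts
methylated epialleles and is observed as U / I / M.  One generation is
T = S(s) · E(α, β): segregation S sends heterozygotes to (¼, ½, ¼)
(reweighted (1−s, 1−s/2, 1) under ABmm — selection against unmethylated
products — or (1, 1−s/2, 1−s) under ABuu, then renormalised), and E applies
per-allele epimutation independently (gain α on unmethylated, loss β on
methylated alleles).  ABneutral fixes s = 0; ABnull is the identity.
Applying epimutation before segregation differs only at O(αβ) per
generation; S-then-E is the default order.

With the founder at the stationary distribution π of T, the expected
divergence of two descendants at branch lengths (t_i, t_j) is

    E[D] = c + Σ_a π_a Σ_{x,y} (T^{t_i})_{a,x} (T^{t_j})_{a,y} w(x,y)

with w the divergence weights and c an intercept absorbing measurement
noise.

**Identifiability.**  E[D] is *exactly* invariant under swapping α and β
(the relabelling U↔M maps one chain onto the other and w is symmetric), and
is nearly flat along a ridge that trades the two rates off.  The
equilibrium assumption resolves this: the chain's stationary methylated
fraction π₂(α, β, s) must reproduce the observed fraction of M calls.  The
fit therefore appends one anchor residual (π₂ − observed M fraction) to the
divergence residuals; with it, both rates are recovered to a few percent at
the study conditions, without it the orientation of the two rates is
arbitrary.  The residual sum of squares reported for model comparison
covers the divergence residuals only.

Fitting is bounded non-linear least squares in log₁₀(α), log₁₀(β) (bounds
10⁻¹²–0.1), s ∈ [0, 0.99] and intercept c, with multi-start over
log-uniform rate draws (fixed seed).  The optimiser's intercept bound is
[−0.05, 1]: clamping at zero biases both rates downward by about 1% when
the true intercept is near zero, because noise that favours a negative
intercept is absorbed by the slope instead; reported intercepts may
therefore be marginally negative, while the physical intercept is a
non-negative noise floor.  ABnull is fitted in closed form (c = mean D).

**Uncertainty.**  Pairwise divergences share regions and lineages, so
residuals across pairs are far from exchangeable — a residual bootstrap
understates the estimator variance severely (measured interval coverage
≈ 45% at nominal 95%).  The default is therefore a region-level case
bootstrap: regions are resampled with replacement (multinomial weights),
every pairwise divergence and the equilibrium anchor are recomputed, and
the model is refitted from the point estimate.  Intervals are basic
(reflected) percentile intervals, which correct the median bias induced by
bound clamping; measured coverage at the study conditions is ≈ 90–93% per
rate.  A plain residual bootstrap remains available in `fit_model`.

**Model comparison.**  Nested F-tests on divergence RSS: ABnull (1
parameter) vs ABneutral (3), ABneutral vs ABmm / ABuu (4).  ABneutral is
retained unless a selection model is significant at 0.05; ABnull is chosen
when accumulation itself is not significant.

## Stratification

Regions get a feature label when the overlap covers ≥ 40% of the *region*
span (region-relative, since regions are the analysis unit); regions with
no label are intergenic; multiple labels are allowed.  Promoters are
1.5 kb upstream of each TSS, strand-aware, clamped at chromosome bounds.
gbM status is consumed as a gene-id list, not recomputed.  CG shape
classes: duplet (a single CG dyad) vs multiplet, dense/sparse against the
density median 0.105 and short/long against the span median 104 bp (ties
to the lower class; medians recomputable from data).  Chromosome zone
(arm / pericentromere / centromere) is assigned by region midpoint —
regions are ≤ 185 bp, tiny against zones.  Stratified fits rerun
divergence + model fitting on each stratum's retained regions; strata
under a configurable minimum (default 50 regions) are flagged unstable.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: pedigree layouts with the
published branch counts and sampled generations (MA1_1: 12 branches,
sampled at generations 3/31/32; MA1_2: 7 branches at 3 and 31; MA1_3: one
branch at nine generations; MA2_3: two branches at five generations — the
exact per-branch generation assignment within those constraints is the
package's own choice, as is the generation spacing for MA1_3/MA2_3),
founder states at the model equilibrium, per-region independent
inheritance, status-conditional read emission (methylation probabilities
0.02 / 0.5 / 0.9 for U / I / M, matching the observed per-status region
level distributions, with bisulfite non-conversion folded into the U
level) and negative-binomial coverage (mean 10, shape 5 — realistic WGBS
depth).  Default rates are the genome-wide CG averages α = 1.2·10⁻⁴,
β = 4.6·10⁻⁴ per haploid epiallele per generation.

Not emulated: linkage between neighbouring regions, coverage correlation
along the genome, mapping artefacts, context interactions, or selection on
whole plants.  Passing tests therefore demonstrate correctness of the
estimator under its own assumptions — they do not validate those
assumptions on real methylomes.

Large simulation studies use `synthetic_regions` (region shapes mimicking
segmentation output on a virtual chromosome) so no genome sequence needs
materialising; the genome-based path (`simulate_genome` → `segment`) is
exercised at smaller scale in the pipeline tests.

## Problem sizes and calibration measurements

The headline recovery check runs 12 replicates of the full pipeline at
5·10⁴ regions on the MA1_1 layout (the published analyses use one fit per
pedigree at genome scale; 12 replicates keep the check to a few minutes on
one CPU).  Measured there: relative errors of both rates ≤ 5–6% in every
replicate, region-bootstrap interval coverage 22/24 rate-replicate events.
The forward-simulation oracle for E[D] uses 10⁶ loci over a 3×3 rate grid
at three time depths (agreement within 3 SE).  Model selection uses 12
neutral-truth batches (ABneutral kept in all 12) and 7 selection-truth
batches.

## Known limitations

- **No power against selection from divergence curves.**  ABneutral with
  free rates and intercept reproduces ABmm/ABuu expected-divergence curves
  to well below sampling noise at any realistic region count (mimicry rms
  < 1% of the per-pair sampling SE at 5·10⁴ regions, s = 0.5).  The nested
  F-tests are therefore honest but nearly powerless against mild selection;
  in practice a selection model is only selected when noise happens to
  favour it.  This is consistent with neutral fits being preferred on all
  real pedigrees and contexts.
- Mixture-based calling can shift borderline I calls relative to an
  HMM-based caller; the divergence weights bound the impact of any single
  call at 0.5/N.
- The equilibrium anchor assumes genome-wide methylation is stationary; on
  systems far from equilibrium the orientation of α vs β would have to
  come from external information.
- Bootstrap intervals undercover mildly (≈ 90–93% at nominal 95%) because
  the fitted curve is close to interpolating the few dozen pairwise means.
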