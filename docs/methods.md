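# Methods

`loopshift` analyzes binned intra-chromosomal chromosome-conformation contact
matrices (TCC / in situ Hi-C style) together with the annotation tracks and
super-resolution imaging data that accompany studies of chromatin-loop
dynamics between cell states. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic-data experiments
do and do not demonstrate.

## Normalization and the expected model

Raw counts are modelled as C_ij ≈ b_i · b_j · T_ij, where b_i is a per-bin
visibility bias and T the bias-free contact propensity. Biases are estimated
by iterative proportional fitting (IPF): each of 20 iterations rescales b by
the current relative coverage of N = C/(b bᵀ), driving the marginals of N
toward uniformity. Conventions:

* bins with zero marginal count are masked before fitting (IPF diverges on
  empty marginals) and excluded from all downstream statistics;
* b is reported with geometric mean 1 over unmasked bins, making bias
  vectors comparable across samples (IPF only identifies b up to scale);
* diagonal entries participate in the IPF marginals (counted once); the
  r = 0 diagonal is never used downstream.

The distance-decay curve E(r) is the per-distance mean of N over unmasked
bin pairs — structural zeros included — smoothed by an unweighted running
mean over the integer distances {r−1, r, r+1} (the integers within a
half-window of 1.5 bins), truncated to the available range at the curve
ends. The expected count for a pair is S_ij = b_i b_j E(|i−j|).

A structural caveat, visible in simulation: when the underlying matrix is a
pure decay profile, its marginals are not flat (chromosome ends see fewer
partners), so IPF absorbs a smooth positional ramp into b. The product
b_i b_j E(r) then carries a smooth percent-level position-dependent error
that is shared between replicates. The loop caller's local-background stage
(below) is designed to be insensitive to it; the bias-recovery correlation
on planted log-normal biases is ≥ 0.99 at 2,000 bins and slightly lower on
very short chromosomes, where the ramp is proportionally larger.

## Interaction testing

Pixels within 2 Mb of the diagonal with at least one raw count in every
replicate are putative interactions. Counts and expected counts are summed
over the 3×3 square centered on the pixel (sums, not means, so aggregates
remain counts; the square must lie strictly above the diagonal). Each pixel
is fit with an intercept-only negative-binomial regression, log link,
offset log S′ per replicate:

    C′_k ~ NB(mu_k, alpha),  log mu_k = beta + log S′_k,  Var = mu + alpha·mu²

The Wald statistic uses the observed Fisher information at the maximum;
dispersion is treated as fixed during testing (two-stage). A one-sided test
of H0: β ≤ 0, Benjamini–Hochberg adjustment pooled over all tested pixels
(no independent filtering), and the call rule adjusted p < 0.20 with fold
change > 1.5 define significant interactions. The Newton solver is
vectorized over millions of pixels; a single fit agrees with a brute-force
likelihood maximization to 1e-6 relative (tested).

### Dispersion

Dispersions are estimated by conditional maximum likelihood within ~50
equal-occupancy bins of the mean count, smoothed across bins with a 5-bin
moving average and floored at 1e-8. Conditioning on each group's replicate
sum eliminates the per-pixel mean exactly when within-group offsets are
equal, which avoids the downward bias of plug-in ML with two replicates.
The estimate reflects replicate-to-replicate variation only; model misfit
that is shared between replicates must be handled elsewhere (see the local
background stage). Zero replicate variance yields the floor.

## Loop detection

Significant pixels are distilled into loops in four steps.

1. **Local background.** On the replicate-pooled normalized matrix, the
   center pixel must exceed region-specific multiples of the mean over four
   diagonal-truncated neighborhoods — donut (Chebyshev radii 2–5) and
   lower-left quadrant at 1.75×, horizontal and vertical stripes at 1.5×
   (the enrichment thresholds conventional for focal-loop callers) — and
   its raw count must clear a Poisson upper tail at 1e-3 against each
   region-rescaled local expected λ_f = S_center · (Σ_f raw / Σ_f S).
   Rescaling by the surrounding observed/expected ratio cancels smooth
   positional error in S. These constants were calibrated once on
   planted-loop simulations and are exposed as parameters.
2. **Clustering.** Surviving pixels are clustered by 8-connectivity; a
   cluster's anchors span its constituent bins, extended by 10 kb on both
   sides; the representative pixel is the one with the smallest p.
3. **Separation.** Clusters whose anchor midpoints are separated by less
   than 120 kb are dropped (the detection geometry cannot resolve closer
   pairs).
4. **Merging and the singleton guard.** Records whose anchors occupy
   consecutive bins of another record's anchors are merged and counted
   once. Clusters of a single pixel are kept only when their best p-value
   is below 1e-10: a genuine focal loop enriches its whole 3×3 footprint
   and virtually always surfaces as a multi-pixel cluster, whereas isolated
   significant pixels are dominated by count noise. On simulations with 50
   planted 3× loops among ~2×10⁶ tested pixels this caller attains recall
   ≥ 0.86 with empirical FDR ≤ 0.05 across seeds.

## Differential loop strength

For the union of loops found in two conditions, counts and expected counts
are aggregated per sample over each loop's 3×3 interaction area; overlapping
areas are merged before testing. With per-condition intercept fits (the
saturated two-group NB model factorizes), γ = (β₂ − β₁)/ln 2 is the log2
fold change, its Wald variance the sum of the per-condition inverse observed
informations, and the two-sided p-values are BH-adjusted per comparison.
Classification: *induced* (adj. p < FDR and 2^γ > 1.5), *reduced*
(symmetric), *common* (2^|γ| < 1.25), otherwise *indeterminate*. The
condition label swap exactly negates γ and exchanges induced and reduced
(tested). On 2,000 null areas the induced+reduced rate at FDR 0.1 is < 1%.

## Topology metrics

**Directionality index.** With A_i and B_i the summed normalized signal in
2 Mb windows left and right of bin i,
DI_i = sign(B−A)·(A−B)²/(A+B) — algebraically identical to the
chi-square-like form with E = (A+B)/2. Bins whose window leaves the
chromosome, or with A+B = 0, are undefined and excluded from summaries.

**Insulation score.** IS_b = log2(0.5·(L′+R′)/X′), where X′ sums the 5×5
normalized square centered on (b−Z, b+Z) with Z = 5, and L′/R′ are the same
square translated by D = 15 bins toward 5′/3′. Defaults are tuned to 10-kb
bins: D clears the ~5-pixel stripe a loop projects into its domain while
staying inside the flanking domains; both Z and D are parameters. IS is
invariant under global scaling and undefined where any square leaves the
matrix or X′ = 0.

**Compartments.** At 50-kb resolution the coverage-normalized matrix is
detrended by a per-distance histogram mode (Freedman–Diaconis bin width,
falling back to the mean for sparse distances) smoothed by a cubic spline in
log–log space. Among the first three eigenvectors of the correlation matrix
of the detrended matrix, the one maximizing (mean within-sign-group
correlation − between-group correlation) is chosen — an automated stand-in
for visual selection. The sign is fixed so the bin group with higher
aggregate expression is positive ("A"). Chromosomes shorter than 20 bins
are rejected.

**Domains.** Contact domains are inputs (called externally). A *loop
domain* has both boundaries (±20 kb) intersecting the two anchors (±20 kb)
of a single loop; an *ordinary* domain contains no internal loop (both
anchor midpoints strictly inside) and is not nested in a loop domain;
everything else is *other*. Boundary intervals are ±15 kb around each end;
a domain is in compartment A when strictly more than 50% of its fully
contained 50-kb bins are labelled A (ties go to B).

## Regulatory annotation

Overlap is any-bp intersection on 0-based half-open intervals, strand
ignored. Promoters are TSS ± 100 bp, active when overlapping H3K4me3;
putative enhancers are H3K4me1 peaks overlapping neither H3K4me3 nor a
promoter, active when overlapping H3K27ac, else poised; induced enhancers
are condition-2 actives overlapping no condition-1 active. Motif
orientation comes from the best hit with p strictly below 1e-4 (ties broken
leftmost). Differential occupancy uses median-of-ratios size factors as
offsets in the same NB Wald machinery, with dispersions estimated on
size-factor-scaled counts; *gained* means adjusted p < 0.1 with a
normalized condition-2/condition-1 ratio strictly above 1. With
Var = μ + αμ², the asymptotic Wald z for a 2-fold change is
ln 2 / sqrt(2α/R); at α = 0.05 this gives ~3.1 for R = 2 replicates —
enough to rank and localize gained peaks, but ≥ 80% recovery at BH 0.1
requires R ≈ 4.

Tile profiles rescale each loop domain (anchor midpoint to anchor midpoint)
to 250 core tiles plus 10 flanking tiles per side (270 values, each the
fraction of domains with ≥ 1 overlapping feature of a class). A feature
exactly at the domain start touches flank tile 10 and core tile 11 (1-based);
profile maxima are therefore reported over core tiles. Promoter–enhancer
contact ratios trim domains 20 kb inward, require pair spans ≥ 20 kb, and
drop pairs with zero condition-1 contact (undefined ratio) and domains with
no qualifying pair.

## Replication-fork imaging

Events below 500 photons are discarded; the rest are binned onto a 10-nm
grid by counting. Fork detection: 3×3 median filter; removal of foreground
(nonzero) pixels with fewer than 3 foreground 8-neighbors; grayscale
dilation with a disc of radius 4 pixels (pixels at center distance ≤ 4,
i.e. 49 pixels); maxima are foreground pixels where dilated − original = 0;
one fork is kept per 8-connected plateau (lexicographically smallest
pixel). The connectivity filter runs after the median filter, matching the
order the processing steps are described in. Ties between non-adjacent
equal maxima inside one focus would double-count; in practice the median
filter makes the top level set of a unimodal focus connected, and on
planted fields of 100 clusters (σ = 20 nm, 200 events each) the detected
count is within ±2 of truth. NND is Euclidean, center-to-center, in nm.

## Synthetic data

The contact generator draws counts NB(μ, α) with
μ_ij = b_i b_j · c (1+r)^(−a) × domain × compartment × loop factors, the
(1+r) form avoiding the r = 0 singularity. Defaults: one 20-Mb chromosome
at 10-kb bins (2,000 bins), c = 400, a = 1, log-normal biases with σ = 0.5,
dispersion α = 0.1, two replicates — chosen so per-pixel means span the
range from tens near the diagonal to ~2 at 2 Mb, comparable to a
well-sequenced experiment at this resolution. Condition effects multiply
selected loop footprints in condition 2. The annotation generator places
CTCF peaks with convergent motifs at loop anchors (forward at 5′, reverse
at 3′) plus uniform background peaks, and occupancy counts with a 2× gain
at anchors of induced loops. The localization generator uses Gaussian
clusters with log-normal photons (median 800, log-sd 0.5).

What the simulations do **not** emulate: polymer-physics contact
correlations, translocations/copy number, TAD nesting hierarchies,
chromatin-state-dependent peak widths, read-level artifacts, or imaging
drift. Passing recovery tests therefore demonstrates correctness of the
statistics under the assumed generative model, not robustness to every
property of real data.

## Numerical choices

* NB parameterization Var = μ + αμ² everywhere; dispersion floor 1e-8.
* Newton steps for the NB intercept are clipped to ±3 on the log scale;
  convergence tolerance 1e-12 (oracle agreement tested to 1e-6 relative).
* BH adjustment is pooled per run (per genome), per comparison.
* Ties in loop-cluster representatives, plateau deduplication, and motif
  best hits are broken deterministically (smallest p, lexicographic pixel,
  leftmost hit).
* All generators are pure functions of their arguments and a single integer
  seed; identical seeds give byte-identical outputs.

## Known limitations

* Inter-chromosomal contacts are out of scope; all statistics are
  intra-chromosomal.
* The expected model's positional ramp (above) is intrinsic to balancing
  decay matrices; downstream stages compensate, but β̂ for individual
  pixels retains percent-level systematic error on synthetic data.
* Differential-occupancy power at two replicates is bounded by the
  dispersion (see above); this mirrors the design limits of real two-
  replicate ChIP comparisons.
* Domain callers and peak callers are not reimplemented; their outputs are
  inputs here.
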