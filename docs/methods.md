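# Methods

## Measurement model and estimation

A CpG in one culture is measured twice: a conventional bisulfite (BS)
channel whose methylated fraction reads 5mC + 5hmC, and an oxidative
bisulfite (oxBS) channel that reads 5mC alone. Arrays deliver continuous
beta values without read counts, so the package works with pseudo-counts
`x = round(beta * N)` at a per-cell pseudo-coverage `N` (default 1000,
logged in every run manifest). `N` stands in for array intensity as the
binomial weight of each observation; it is a declared modelling device,
not an estimate of any physical quantity.

The joint likelihood

    x_bs ~ Binomial(n_bs, m + h),   x_ox ~ Binomial(n_ox, m)

is maximized over the simplex `m >= 0, h >= 0, m + h <= 1`. The optimum
has a closed form: interior (`m_hat = x_ox/n_ox`,
`h_hat = x_bs/n_bs - x_ox/n_ox`) when the BS rate is at least the oxBS
rate, and the boundary `h = 0` otherwise, where both channels measure the
same quantity and the MLE pools the counts,
`m_hat = (x_bs + x_ox)/(n_bs + n_ox)`. Negative naive differences are
reported as NA 5hmC (the field's convention); the boundary `m_hat` is
still reported because the 5mC estimate stays meaningful. Ties
(`beta_bs == beta_ox`) resolve to the interior solution, i.e. `h_hat = 0`
defined. The closed form is verified in the test suite against an
exhaustive 1e-4-lattice maximization of the likelihood (the lattice
optimum is computed exactly via the separability of the log-likelihood in
`q = m + h` and `m` plus a running maximum, so the oracle is a true grid
search, not a heuristic).

Consequence worth knowing: averaging only the defined (non-NA) `h_hat`
cells overstates the mean 5hmC wherever true 5hmC is small relative to
the binomial noise, because the negative half of the noise distribution
is censored. At `N = 1000` and the default truth this bias is about
+0.2 to +0.3 percentage points for the proliferative condition (true mean
2.2%) and fades as 5hmC rises. The pipeline reports NA fractions next to
every summary so the censoring is visible; it never imputes.

## Synthetic data: what it emulates, what it does not

The generator produces a single 5 Mb toy chromosome with 50 non-overlapping
genes (default), exon/intron structure, CGIs at 60% of TSSs, a
promoter/elongation/weak-transcription/heterochromatin state tiling, and
gene-set labels (25% up-regulated, 25% down-regulated, 10% housekeeping).
Probes are placed like a sparse methylation array: 10 gene-body probes per
gene laid out in 2-3 CpG-dense clusters (within-cluster spacing
100-300 bp — CpG density on real arrays is clustered, and region calling
at a 1 kb proximity window is meaningless without it), 2 promoter probes,
1 probe per CGI, and intergenic probes every 40 kb; ~725 probes in all.

Latent truth per condition:

- 5mC is a two-component beta mixture (hyper-methylated mean 0.88,
  hypo-methylated mean 0.08, concentration 80) — the canonical bimodal
  shape of methylome beta values. The mixture membership threshold is
  solved per condition on the realized draws (bisection on the shared
  per-probe latent, monotone by construction) so that the gene-body mean
  hits the condition target exactly; a sub-granularity multiplicative
  residual finishes the calibration. Promoter and CGI probes are
  hypomethylated (mean 0.12). Component membership is shared across
  conditions through one latent uniform per probe, so a CpG's
  hyper/hypo identity is stable and only a small margin of probes shifts
  between conditions.
- 5hmC in the proliferative (reference) condition is a high-concentration
  beta draw (kappa = 300) around context means: gene bodies at the target
  (2.2%), promoters/CGIs depressed (x0.30 / x0.25), intergenic x0.7.
  Differentiating and adenosine-derivative conditions add a non-negative
  gain on top of the reference, weighted by gene set (up x1.6, none x1.0,
  housekeeping x0.9, down x0.8) and intron/exon (x1.15 / x0.8), scaled so
  the gene-body mean hits the condition target (4.1% / 3.5%). Because the
  gain is non-negative and shares the reference quantile, the
  differentiating hydroxymethylome dominates the proliferative one
  pointwise on gene bodies.
- Strong-gain clusters: one whole body-probe cluster (>= 3 CpGs, true
  h ~= 0.30) on each of 5 up-regulated genes in the differentiating
  condition and 3 in the adenosine-derivative condition. These give the
  default pipeline position calls at the 20% delta-beta threshold and
  proximity regions, mirroring (at desk scale) the DhMP/DhMR structure
  such experiments report. Pinned clusters are excluded from the mean
  recalibration so their effect size survives calibration; on very small
  toy genomes the planted set shrinks automatically until the gene-body
  mean target stays feasible.

Measurement: independent binomial draws per probe x sample at coverage
`N`; detection p-values are small (< 0.005) for ordinary cells and
elevated for failed cells. Ordinary probes fail per cell at rate 0.005; a
planted 5% subpopulation of bad probes fails at rate 0.5, giving the
detection filter deterministic targets (with 14 pooled samples a bad
probe survives with probability < 1e-3).

Not modelled, deliberately: Infinium type-I/II probe chemistry, dye bias,
batch effects, cross-reactive probes, sequence context, biological
replicate heterogeneity beyond binomial noise, and any genome beyond the
single toy chromosome. Passing tests therefore demonstrate correctness of
the estimators and calls under the declared binomial measurement model —
not robustness to array artefacts that real preprocessing (e.g. SWAN)
exists to absorb.

## Quality control and normalization

Probe QC pools BS and oxBS samples into one panel and removes a probe
from both matrices iff its detection p exceeds 0.01 in strictly more than
10% of the pooled samples ("more than" is strict: failing in exactly 10%
keeps the probe). Joint filtering keeps the matrices paired; whether the
original pipeline filtered per channel is not documented, so the joint
rule is this package's documented choice. The filter is idempotent.

The normalization slot is stratified quantile normalization: within each
probe stratum, every sample is mapped onto the across-sample mean
quantile function (rank-preserving, NaN-aware, output clipped to [0, 1]).
It is OFF by default because the binomial simulator needs no
normalization; SWAN proper requires Infinium I/II chemistry annotations
that this data model does not carry. Strata with fewer than two probes
are left untouched with a warning.

## Differential testing

Per probe, a two-group ordinary least squares fit (after per-probe NA
removal) yields `delta = mean(target) - mean(reference)`, pooled residual
variance `s2`, and `df = n1 + n2 - 2`. Probes with fewer than two defined
samples in either group are untestable: they are excluded from both
moderation and BH (not assigned p = 1) so they cannot dilute the FDR, and
are reported separately.

Variance moderation follows the standard moderated-t construction. With
`e = log(s2) - digamma(df/2) + log(df/2)` (unbiased for `log(s0^2)` under
the scaled-chi-square sampling model), the prior degrees of freedom `d0`
solve `trigamma(d0/2) = var(e) - mean(trigamma(df/2))` by Newton
inversion (tolerance 1e-8; `d0 > 1e6` is treated as infinite), and
`s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2))`. Posterior variance is
`s2_post = (d0 s0^2 + df s2)/(d0 + df)`;
`t = delta / (sqrt(s2_post) * stdev_unscaled)` with `d0 + df` degrees of
freedom (normal when infinite). `prior_df = 0` recovers the classical t
exactly; an observed-variance ensemble with no excess spread yields
`d0 = inf` and complete shrinkage to the common `s0^2`. The
implementation is cross-checked in the test suite against the
Bioconductor reference implementation of this construction (limma, via
Rscript) to 1e-6 on the statistics, and its null type-I error at 0.05 is
verified to sit in [0.035, 0.065] over 100k simulated null probes.
Degenerate input (every residual variance zero) raises an error
suggesting more replicates or jitter rather than producing infinite t.

Calls: a position is significant iff `fdr < alpha` (strict) and
`|delta| >= delta_min`. Two delta thresholds coexist in the pipeline by
design, both exposed as parameters: 10% — the sensitivity floor of the
paired-conversion technique — for 5hmC peak calls and region membership,
and 20% for the DhMP/DMP heatmap-style calls. Peaks use a one-sided test
(a peak is signal loss after oxidation, i.e. gain only); group contrasts
are two-sided. With `alpha >= 1` the FDR clause of peak calling is
disabled so that `min_delta = 0` returns exactly the positive-delta
probes.

Regions are transparent proximity clusters: consecutive significant CpGs
with successive gaps <= 1 kb (the conventional proximity window), kept at
>= 3 CpGs, spanning [first CpG, last CpG + 1). The region statistic is
the Stouffer combination `z = sum(z_i)/sqrt(k)` of member signed
z-scores, two-sided p, BH across regions, and a BED score of
`-log10(FDR) x 100` capped at 1000. This replaces kernel-smoothed region
statistics: the smoothing bandwidth and model of those methods are not
reproducible from a one-line description, whereas the proximity rule is
fully specified, auditable, and testable. Region FDRs are interpretable
as combined-evidence summaries, not kernel-corrected genome-wide rates.

Unpaired condition comparisons of averages (e.g. per-gene body means) use
the two-sided Mann-Whitney rank-sum test: exact enumeration when
`n_a + n_b <= 12` without ties, normal approximation with tie correction
otherwise; identical constant groups return p = 1 with a warning.

## Genomic context

Feature annotation uses precedence promoter > exon > intron > intergenic
with the promoter window (-2000, +500) bp around the TSS in gene
orientation — a documented, configurable convention (the window size is
not something the underlying study defines). The toy gene models carry no
CDS/UTR structure, so no UTR feature classes exist. CGI context uses the
universal distances: island inside a CGI, shore within 2 kb of an island
edge, shelf within 2-4 kb, open sea beyond. Nearest gene is by absolute
TSS distance with deterministic lexicographic tie-breaks; signed
distances are negative upstream of the TSS in gene orientation.

Enrichment against the array background uses per-category 2x2 tables
(in/out of category x foreground / background-minus-foreground),
two-sided Fisher exact p, sample odds ratio with Haldane +0.5 only when a
zero cell occurs, and BH across categories. A foreground equal to its
background is neutral by definition (OR = 1, p = 1) — the
background-minus-foreground margin is empty and no table exists.

Metagene profiles scale each gene body to 20 bins TSS->TES in gene
orientation (minus-strand genes flipped) with five fixed-width bins per
2 kb flank; bin means ignore missing signal and per-bin assignment counts
are reported, so binning conserves probe mass. Bin counts and flank sizes
are package defaults, not values inferred from any figure.

The gene-set overlap test is the exact hypergeometric upper tail
P[X >= k] with fold enrichment `k / (|A||B|/|U|)`; it is verified against
a 1e5-draw permutation oracle in the tests.

## Pipeline, reproducibility, problem sizes

One YAML-serializable config drives simulate -> QC -> (optional
normalization) -> estimation -> peaks -> differential -> regions ->
context -> report; every stage failure names the stage; outputs carry a
manifest with the config, its digest, the seed, and package versions.
All randomness flows through explicit seeds (numpy `SeedSequence`
spawns per stage); identical config + seed reproduces byte-identical
tables modulo the manifest timestamp.

The shipped test and acceptance workloads run at desk scale by choice:
~725 probes x 14 samples for the default experiment, 1000-probe panels
for planted-peak and planted-region calibration (10 seeds each), 5000
null probes x 20 seeds for type-I calibration, and 200 random triples for
the MLE lattice oracle. These sizes keep the full suite under a minute
while leaving every statistical check well-powered; nothing in the
implementation depends on them.

## Known limitations

- The non-NA mean of `h_hat` is upward-biased where true 5hmC is within
  ~2 noise SDs of zero (quantified above); comparisons between conditions
  remain valid because the bias is shared, but absolute low-end 5hmC
  levels should be read together with the NA fraction.
- Pseudo-coverage is a single global weight; real arrays have
  probe-specific precision the data model does not carry.
- Proximity regions do not smooth between non-significant CpGs; a region
  interrupted by a run of sub-threshold CpGs longer than the gap window
  splits.
- The generator's dispersion parameters (m concentration 80, h
  concentration 300, gain pattern weights) are plausible desk-scale
  choices, documented here; they are not estimates of any cell line's
  biology.
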