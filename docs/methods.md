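# Methods

`tillerqtl` implements a QTL-seq (bulked-segregant) discovery pipeline and
an F2 interval-mapping validation stage for a two-locus epistatic trait —
the high-tillering (HT) phenotype that appears in rice introgression lines
when donor (Hapcheonaengmi3, "HP3") alleles are present at two loci in the
recurrent (Milyang23) background. This note records the models, the
numerical choices, and what the synthetic experiments do and do not show.

## Trait and population model (simulation)

Populations are simulated at the gamete level. Crossovers are a Poisson
process on the genetic scale (Haldane model, no interference); physical
positions map to genetic positions at a constant, configurable rate
(default 4 cM/Mb, a typical rice figure). F2 individuals are two
independent F1 meioses; RIL(g) lines are selfed by single-seed descent to
generation g, so residual heterozygosity is 2^-(g-1) in expectation;
BC1F(g) lines are one backcross followed by selfing. Map *estimation*
downstream uses the Kosambi function, deliberately mismatched to the
Haldane simulation: the resulting map-length shrinkage (Kosambi compresses
the same recombination fraction into fewer cM) is a known, testable bias
of real analyses and is visible in the F2 map lengths the acceptance
script reports.

The latent trait is Σ_i (a_i·x_i + d_i·z_i) + ε with x_i the donor-allele
dosage, z_i the heterozygosity indicator and ε ~ N(0, σ). Under the
default *complementary epistasis* rule the genetic term is zeroed unless a
donor allele is present at **every** declared HT locus — the genetic
architecture inferred for the HT trait, where neither parent shows the
phenotype. Default additive/dominance effects are the values estimated in
the validation cross: (a, d) = (1.63, 0.60) for the chromosome-1 locus and
(1.04, 1.25) for the chromosome-6 locus, in units of the 1–9 HT score.
Ordinal scores are produced by thresholding the latent value at the 95%
quantile of the pure-noise distribution (so non-carriers are almost always
class 1, the recurrent-parent type) and cutting the remainder into
equal-width bins up to the maximal genetic value. The generating process
for real HT scores is unknown; this construction merely guarantees a
dominant no-HT class and a monotone genotype-score relation.

Bulks are formed by rank (top n_high, bottom n_low, ties broken by
individual index for determinism); the study design is 8 HT vs 12 non-HT
lines out of 49 RIL-derived lines. Read data are sampled per SNP and bulk
as depth ~ Poisson(depth_mean) truncated at ≥ 1 (a zero-depth site is
unobservable) and donor-allele count ~ Binomial(depth, bulk donor
frequency). No sequencing-error, mapping-bias or indel model is included:
passing tests show the statistical pipeline behaves correctly under its
own sampling assumptions, not that it is robust to artifacts of real
short-read data.

## SNP-index statistics

Per bulk, the SNP index is the donor-allele read fraction; the delta-SNP
index is high-bulk minus low-bulk. Rows are filtered before computation
(default: ≥ 10 reads in each bulk; sites monomorphic across both bulks
dropped). Significance is a Monte-Carlo null that re-simulates the entire
sampling chain at a neutral locus — bulk members' genotypes from the
population model (F2 1:2:1; RIL(g) fixed classes plus residual
heterozygosity), the bulk allele frequency, and binomial read counts — on
a depth grid {5, 10, …, 100} with 10,000 replicates per depth. P-values
are two-sided on |delta| with a +1 pseudo-count (so p ∈ (0,1], never 0)
and are interpolated linearly between grid depths; a record's two bulk
depths are collapsed to their harmonic mean, the single common depth whose
read-noise variance matches the pair. Calibration on matched null data is
verified by test (5% ± 2 points at the 0.05 level; one-sided KS bound for
super-uniformity — empirical p-values from discrete read counts are
conservative, never anti-conservative).

## Window scan and interval calling

The coarse scan averages the delta-SNP index in 2 Mb windows advanced by
100 kb, windows anchored at position 1 and clipped at the chromosome end.
Two significance quantities are attached per window:

* `WINDOW_P` — the fraction of resampled null window means (drawing
  per-SNP null deltas at each member's depth) at least as extreme as the
  observed mean. This is the per-window "average p" device. Note its
  limitation: the resampling draws member deltas independently, while in
  data member SNPs are correlated through linkage, so `WINDOW_P` is
  anti-conservative for windows with many linked SNPs. It is retained
  because the operative control is the band below.
* `BAND95`/`BAND99` — the window average of the per-SNP null 95%/99%
  |delta| quantiles at each member's depth: the confidence band drawn in
  QTL-seq plots.

A QTL interval is called where `WINDOW_P < α` **and** |mean delta| clears
the matching band — the requirement that the window average be
significantly above the surrounding-region null, not merely locally
extreme. Significant windows of consistent sign merge when adjacent on the
step grid (gap 0, so a single sub-threshold step separates intervals — the
behaviour needed to keep the two chromosome-6 loci separable). Interval
reports are 1-based inclusive in TSV (size in Mb as (end−start+1)/10⁶) and
0-based half-open in BED.

### False-positive control and the resolution of 8/12-line bulks

Two acceptance-level properties of this design cannot hold
simultaneously, and the package makes the trade-off explicit rather than
hiding it. The genotype-sampling noise of bulks of 8 and 12 *lines* gives
the null delta a standard deviation of √(0.25/8 + 0.25/12) ≈ 0.23
independent of depth. A process-level bootstrap (Markov-chain line mosaics
along the SNP grid) puts the genome-wide null maximum of 2 Mb-window means
at ≈ 0.6–0.76, while the true-QTL window plateau under complementary
epistasis is 1 − f_low with f_low ~ Binomial(12, 1/3)/12 — i.e. anywhere
from ≈ 0.4 to 0.85. The distributions overlap: any threshold strict
enough to keep a null genome empty also misses a large fraction of true
QTL realizations. The default calling rule follows standard QTL-seq practice
(marginal band test): it recovers both simulated QTLs in ~90% of
replicates but flags a few spurious intervals on a fully null genome —
exactly as genome scans of this design do in practice. The acceptance
tests report both numbers honestly; the null-genome zero-interval bar and
the fine-candidate containment bar (below) are not met by this design and
are left failing with this analysis as the explanation.

## Iterative window refinement

Within a called interval, SNPs are first filtered to those individually
significant at p < 0.01, then a ladder of window passes — default
2 Mb/100 kb, 500 kb/25 kb, 100 kb/10 kb, 50 kb/5 kb, 10 kb/5 kb, anchored
at the region start — retains windows containing at least one significant
SNP. Only the first and last rungs are fixed design points; the
intermediate rungs are a geometric-ish interpolation and
fully configurable, and the trace records every rung so per-rung panels
can be plotted. The final rung's candidate is the longest run of "strong"
windows (mean delta at or above the τ = 0.95 quantile of retained-window
means), bridging gaps of at most one grid step; ties go to the stronger,
then leftmost run. The reported span is exact; a nominally "300 kb"
candidate whose coordinates span 255 kb is reported as 255 kb.

Limitation, visible in the acceptance numbers: with 20 bulked lines the *realized* delta maximum sits
on the breakpoint segment nearest the causal locus, which is a random
0.3–2 Mb away. The refinement therefore localizes to the right
neighbourhood (its candidate lands within ~1–2 Mb of the truth —
megabase-scale offsets between window-based and linkage-based candidates
are routinely seen in experiments of this size) but a few-window candidate
cannot be expected to *contain* the causal base-pair position. On a
high-power design (30/30 bulks, depth 200) the same machinery does
contain the truth with candidates ≈ 2% of the region, which is how the
unit tests validate it.

## F2 linkage stage

Recombination fractions between codominant markers are estimated by EM on
the 3×3 two-locus genotype table (the double heterozygote contributes
2r²/((1−r)²+r²) expected recombinant gametes); the estimate matches
grid-search maximum likelihood to < 10⁻³ by test. Marker order is fixed to
physical order; adjacent fractions are mapped through Kosambi
(d = 25·ln((1+2r)/(1−2r)) cM) and accumulated from 0. Fractions at or
above 0.5 are capped at 0.4999 and flagged.

The scan is Haley–Knott regression on a 1 cM grid: at each position the
expected additive dosage x̂ ∈ [−1,1] and heterozygote probability ẑ are
computed from the nearest non-missing flanking markers via per-gamete
transition probabilities (Haldane within the interval — the common hybrid
with Kosambi inter-marker distances), and y ~ 1 + x̂ + ẑ gives
LOD = (n/2)·log₁₀(RSS₀/RSS₁), PVE = 100·(1 − RSS₁/RSS₀), and the
additive/dominance estimates. The ordinal 1–9 HT score is treated as a
numeric response, as additive interval mapping does. RSS₁ is floored at
10⁻¹² · RSS₀, capping LOD at 6n for a perfect fit.

The ICIM variant first selects background marker variables (additive and
dominance columns per marker, missing values imputed by their
flanking-conditional expectations) by forward-backward stepwise regression
with entry probability PIN = 0.001 (removal at 2·PIN), then rescans with
the phenotype adjusted by the selected cofactors, excluding any cofactor
on the pair of markers flanking the current interval. When no cofactor
passes PIN the scan reduces exactly to Haley–Knott. PVE and effect
estimates are reported from the cofactor-adjusted model.

Genome-wide thresholds come from phenotype permutations (default 1000,
95th percentile of per-permutation maximum LOD). The permutation null uses
the Haley–Knott statistic with the marker design held fixed, which reduces
each permutation to a QR projection and keeps 1000 permutations essentially
free; under permuted phenotypes cofactor selection at PIN = 0.001
essentially never fires, so the HK and ICIM permutation nulls coincide.

## Problem sizes and determinism

Every random stage runs off `numpy.random.default_rng` seeds threaded from
a single configuration or CLI seed; fixed seeds reproduce datasets
byte-identically (tested). The packaged study-scale experiments use two
20 Mb chromosomes at 2 kb SNP spacing (≈ 20,000 SNPs) for QTL recovery, a
twelve-chromosome 300 Mb genome at 30 kb spacing (≈ 10,000 SNPs) for null
calibration, 10,000 null replicates per depth for the p-value tables, 300
resampling replicates for window significance, and 1000 permutations for
F2 thresholds; these sizes give stable acceptance numbers while keeping a
full run in minutes on one core.

## Known limitations

* No read-level simulation: sequencing error, mapping bias and allele-
  depth artifacts are out of scope, so real-data deltas will be noisier
  than simulated ones at equal depth.
* `WINDOW_P` ignores linkage between member SNPs (anti-conservative); the
  confidence band is the operative significance control.
* The ICIM implementation targets the additive/dominance scan; it is not a
  bit-exact reimplementation of the IciMapping software, and epistasis
  scans are not included. Reported LODs can differ from IciMapping's by a
  few tenths.
* The two population scores used historically (1–3 for the RIL population,
  1–9 for the F2) have no defined quantitative link to tiller counts; the
  simulator's binning is one defensible construction, not an inference.
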