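# Methods

`pombepop` re-implements, as a tested and reusable pipeline, the
computational analysis behind a population survey of *Schizosaccharomyces
pombe* natural isolates: multi-locus haplotype collapse, nucleotide
diversity and neutrality statistics, effective population size, pairwise
F_st, linkage disequilibrium with the four-gamete test, growth-curve
fitness-component extraction with an LSC relative-fitness score, and
trait-profile clustering. Because the underlying sequence and phenotype
data were never deposited, every stage is exercised against synthetic
inputs with known ground truth; this note records the models, the
defaults, and what the synthetic results do and do not establish.

## Sequence handling and haplotype collapse

Haploid strains are sequenced at seven non-coding intervals (the
chromosome II centromere central core, the TER1 telomerase-RNA gene, the
large SPBC660.16 intron, and four flanking loci). Printed genome
coordinates are treated as **end-exclusive**: this is the only
convention under which the seven intervals sum to the reported 5,777 bp
total, so the package adopts it throughout (`LocusDef.span = end −
start`).

Site filtering follows the complete-deletion convention: any alignment
column containing a gap is removed ("stripped of indels"), repeat tracts
such as the intron's minisatellite are removed by explicit column
masks, and ambiguous bases (N) are treated like gaps — a conservative
choice for an exact-identity test, since a strain differing only by an
ambiguous call should not found a new haplotype. Strains are then
collapsed into *compound haplotypes*: identity classes of the
concatenated, filtered sequences. Haplotype ids are 1-based in
first-occurrence order of the input strain list; the published table's
numbering is not reproduced because its ordering rule is unstated, but
the partition itself (memberships) is what matters and is what the
tests assert.

## Diversity statistics

For n sequences over L filtered sites:

* π (nucleotide diversity) — mean pairwise Hamming distance over all
  n(n−1)/2 pairs, per sequence and per site. Complete deletion of
  gapped columns is the default (consistent with S); a pairwise-complete
  mode is available.
* Watterson's θ_W = S / a₁ with a₁ = Σ_{i=1}^{n−1} 1/i, computed by
  direct summation.
* Tajima's D = (π_seq − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
  coefficient chain (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂). D is undefined at
  S = 0 and returns NaN with a warning; it also requires n ≥ 4.
* Reported standard deviations of π and θ use the total-variance
  formulas (evolutionary plus sampling variance) classical population-
  genetics packages print; they reproduce the published SDs to ~2 in
  the third decimal but are reporting aids, not tested quantities.
* Effective population size for haploids: Nₑ = π/(2u), with the
  *S. cerevisiae* proxy rate u = 0.33×10⁻⁹ /bp/generation as default,
  and a one-significant-figure rounding helper for headline reporting.

By default `diversity_table` computes statistics over one representative
per compound-haplotype group rather than over all strains — the survey
deliberately discounts clonal resampling of identical isolates — with a
flag to use every sequence.

A documented caveat: the published D values for the centromere and TER1
rows are not consistent with the printed π and S at n = 40 (the intron
row is); the source computation's per-locus sample sizes evidently
differed. Only the internally consistent intron row is asserted.

## Population differentiation

Pairwise F_st uses the pairwise-difference (AMOVA/Hudson) form by
default: F_st = (π_between − π_within)/π_between, with π_within the
average of the two within-population means. This estimator can be
negative, which matches the published matrix containing a negative
entry; a haploid variance-components ("wc") estimator summed over
biallelic sites is provided as an alternative. Haplotypes whose members
have several known origins are assigned to each such population, so
population sizes may sum to more than the number of haplotypes;
populations with fewer than two sequences are excluded with a warning.
Exact reproduction of the published F_st matrix is impossible without
the real sequences and is not attempted.

## Linkage disequilibrium

Informative SNPs are parsimony-informative biallelic columns (minor
allele observed at least twice), carrying genome coordinates through
the column filter. For each marker pair: D = p_AB − p_A p_B; D′ = D/D_max
with sign preserved; r = D/√(p_A p_a p_B p_b); and χ² = n·r² with **no
continuity correction** — the published table satisfies χ² = n·r²
exactly (40·1 = 40; 40·0.85² = 28.9), which rules out a corrected
statistic. Missing genotypes are excluded pairwise and χ² uses the
pairwise-complete sample size. Significance codes star the 5%, 1% and
0.1% points of χ²(1). The four-gamete test flags a pair when all four
gametic types occur; the minimum recombination count Rm is the greedy
disjoint-interval count over incompatible pairs (Hudson–Kaplan interval
reduction).

## Coalescent simulator

The simulator is written directly (it is part of the tested artifact;
an external simulator appears only as a cross-check oracle in one
test). Time is measured in units of 2N generations. For a single deme,
each pair of active lineages coalesces at rate 1; branch lengths
accumulate between events. Mutations are Poisson with mean θ/2 × total
tree length (θ is the per-locus population mutation rate, 2Nₑu·L for
haploids, so E[S] = θ·a₁ and E[π_seq] = θ), placed on branches in
proportion to length under infinite sites: each mutation occupies its
own site, so every segregating site is biallelic. Intra-locus
recombination is out of scope; the `recombination` flag exists for
interface completeness and rejects `True`.

The island model uses d equal demes with symmetric migration: within-
deme pairs coalesce at rate d (deme size N/d), and each lineage
migrates at the scaled rate given by `migration_rate`, choosing a
uniform destination. When `migration_rate = 0` and surviving lineages
are stranded in different demes, the demes are merged into one
ancestral population after a fixed deep split of 5 coalescent time
units — a design choice that makes the isolated-deme limit (F_st → 1)
expressible without adding a divergence-time parameter. Only
qualitative F_st behaviour (≈0 under strong migration, →1 when
isolated, monotone in between) is claimed or tested.

Calibration note: Tajima's D retains a small negative mean under strict
neutrality — the statistic is variance-normalized but skewed. At n = 40
and θ = 5 both this simulator and an independent coalescent simulator
give a mean of ≈ −0.10 to −0.12 over thousands of replicates, so the
suite's calibration bound is |mean D| < 0.15 at 2000 replicates rather
than a band tight around zero.

## Growth curves and fitness components

The synthetic growth model is deliberately the simplest one whose
ground truth is exact: OD is flat at `od_start` until `lag_h`, grows
exponentially at `mu_max`, and is capped at `od_final`, so ln(OD) is
piecewise linear; Gaussian noise is added and ODs are floored at 0.001
(log transforms downstream). True lag, doubling time ln2/μ_max, and
efficiency `od_final − od_start` are known exactly. Defaults emulate
48–72 h Bioscreen microcultivation sampled every 20 min. What the model
does **not** emulate: diauxic shifts, death phases, OD nonlinearity at
high density, or condition-dependent noise; parameter-recovery results
therefore certify the extractor's numerics, not its behaviour on every
real curve shape.

Extraction: OD (blank-subtracted) is smoothed with a 3-point running
median; the maximum specific growth rate is the steepest slope of a
sliding 9-point least-squares line on ln(OD). Candidate windows are
scored by the lower confidence bound slope − 2·SE(slope), so that
low-OD windows — where additive noise produces large ln(OD)
fluctuations — cannot win on noise alone; on noiseless data the score
reduces to the raw maximum slope. A 5-point window was considered and
rejected: at 20-min sampling it is noise-dominated near the inoculation
density (median μ error ~9–15% at noise SD 0.01 versus <5% with 9
points). Lag is the intersection of the max-slope tangent with the
initial ln(OD) baseline (the first smoothed point), doubling time is
ln2 divided by the slope, and efficiency is the smoothed OD range.
Curves whose best slope does not exceed 10⁻³/h are flagged non-growers
and excluded downstream. Measured on 200 synthetic curves at noise SD
0.01, median relative error is <5% for μ and <3% for efficiency, with
lag recovered to within one sampling interval in the median.

The LSC score for strain i and trait j sums squared deviations of the
strain's log measurement from the reference log-mean over runs:

    LSC_ij = Σ_r [ (1/m) Σ_k log(wt_kjr) − log(x_ijr) ]²

generalized to m reference replicates per run (the study design uses
m = 10 and r = 1..2). Efficiency is reciprocal-transformed before the
log (equivalently, its log is negated) so that all three components
point the same way — larger is worse than the reference. The sum over
runs is implemented literally; runs missing on either side are dropped
from the sum rather than imputed.

## Trait profiles

A trait is a fitness component × environment combination (3 × 42 = 126
in the study design); a strain's profile is log2(strain/reference) per
trait, with the *S. cerevisiae* type strain as the reference in the
original design. "Centered Pearson" is read as standard (mean-centered)
Pearson correlation, computed pairwise-complete over shared non-missing
traits; strain pairs sharing fewer than 3 traits are an error rather
than a silent drop. Clustering is average-linkage agglomeration on
1 − r (SciPy's implementation; ties broken by its deterministic
ordering). Group similarity compares same-group against different-group
pairwise correlations with a two-sample t-test — Welch by default, with
a pooled-variance option since the original description says only
"Student t-test". Atypicality correlates each strain against the
per-trait mean profile and ranks ascending (most atypical first); note
that this statistic is only a reliable outlier detector when shared
structure dominates the profiles, as it does for real growth data —
with many small, equally sized synthetic groups the grand mean
correlates weakly with everyone. Per-trait deviation tests a strain's
replicates against all other strains' values per trait and controls the
false discovery rate with Benjamini–Hochberg (the procedure is
unspecified in the original beyond "FDR 5%").

The trait generator plants group means (SD `group_effect_sd`) plus
strain noise, and shifts a chosen fraction of an outlier strain's
traits by `outlier_shift` (default 5) noise SDs in random directions.
It generates independent traits; real trait profiles are strongly
correlated across environments, so passing recovery tests here
demonstrates correctness of the statistics, not their power on
correlated real data.

## The 84-strain collection fixture

`fixture_isolate_collection` emits 84 synthetic strains at the seven
sequenced loci whose exact-identity partition reproduces the published
40 compound-haplotype groups, member for member, with origins as
printed. Sequences are random at the printed locus lengths; each group
carries a per-locus variant signature (two dedicated substituted
columns per variant), arranged so the first two loci jointly distinguish
all 40 groups while the remaining loci show fewer, shared locus-level
haplotypes. The fixture is synthetic: it reproduces the partition
structure, not the real sequences, so diversity values computed from it
are arbitrary.

## Problem sizes and determinism

All generators take integer seeds and are bit-reproducible for a fixed
seed. The test suite's simulation sizes — 2000 coalescent replicates at
n = 40 for estimator calibration, 200 growth curves, 10–15 seeds for
F_st and FDR calibrations — were chosen as the smallest batches at
which the Monte-Carlo error is comfortably below the asserted
tolerances. Pipeline runs embed a config hash and seed in
`run_info.json`, and identical configurations produce byte-identical
reports.

## Known limitations

* No realistic *S. pombe* demography, selection, or intra-locus
  recombination in the coalescent; the island model is symmetric with
  equal deme sizes.
* F_st's citation in the original is ambiguous; both implemented forms
  are defensible readings, neither is asserted to be the original's.
* The replicate structure behind the published per-trait deviation
  claim (n = 2 cultivations) is thin; the test construction here
  (per-trait t-test + BH) is one reasonable reading.
* OD calibration (nonlinearity at high density) is not modelled; no
  calibration data exist in the source.
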