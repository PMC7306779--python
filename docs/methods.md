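# Methods

This note documents the models, estimators and numerical conventions behind
`meiocross`, the assumptions they rest on, and the design choices made where
the underlying methodology is genuinely open.

## Coordinate conventions

All genomic coordinates are 1-based inclusive, the convention of plant
F2 genotype-block tables. The two exceptions are the BED-like crossover
export and bedGraph coverage files, which use the standard 0-based half-open
convention (stated in their headers). A chromosome arm runs from a telomere
to the midpoint of the centromere interval; the midpoint rule is our choice —
arm definitions in the field say only "ends at the centromere" without a
coordinate rule.

## Crossovers from genotype blocks

An F2 individual's chromosome is a sequence of non-overlapping blocks in
states P1 (homozygous parent 1), HET, P2. Each P1↔HET or HET↔P2 step is one
crossover, located in the inter-block interval with the crossover point
taken as the interval midpoint (the marker data only bound the event; the
interval is retained for width-matched randomization). A direct P1↔P2 step
is counted as two crossovers at the same interval, because a single meiotic
crossover cannot produce that step in an F2 — it requires one exchange in
each contributing gamete. Missing-data gaps are treated as part of the
inter-block interval; no imputation is attempted.

## Telomere-distance landscape and the window test

Each crossover midpoint gets a distance to its nearest telomere,
`min(pos − 1, length − pos)`, pooling both arms of all chromosomes onto one
axis. Counts in fixed windows (default 1 Mb) are compared between two
populations with a per-window 2×2 chi-square on (in window vs elsewhere) ×
(population A vs B), Benjamini–Hochberg adjusted (Bonferroni by flag).
Yates continuity correction is off by default; the uncorrected statistic is
very slightly anti-conservative at moderate counts, which our calibration
test bounds empirically. Windows in which both populations have zero counts
are reported with χ² = 0, p = 1, and each window's minimum expected cell
count is exported so users can apply the standard ≥ 5 validity rule, as our
own calibration tests do. Scaled arm profiles assign 10-kb source windows
(or event counts in them) to proportional telomere→centromere bins by
window-center position, pooling all arms; arms shorter than one source
window are skipped with a warning.

## Pollen-tetrad genetics

A three-color tetrad exposes one meiosis across two adjacent intervals.
Classification first computes each interval's ditype (PD/TT/NPD from the
number of spores recombinant between the flanking color loci — always even
under valid 2:2 segregation), which determines the class except for the
TT/TT group, where the overlap between the two intervals' recombinant spore
pairs separates two-strand (D), three-strand (E/F) and four-strand (G)
double crossovers. E and F are not distinguished by any published
convention we could anchor to; we label E the pattern whose surviving
parental spore carries all three colors and F its complement. Tetrads
violating 2:2 segregation are rejected and counted, never silently dropped.

The classifier is verified against an exhaustive oracle that enumerates
every configuration of ≤ 2 crossovers per interval and all chromatid
choices, traces the spores through the exchanges, and labels each reachable
spore multiset by its most parsimonious generating configuration. This also
documents the unavoidable collapses: a two-strand double within one interval
is invisible (classifies as no-crossover) and some three-strand doubles
mimic single crossovers; class labels are therefore observational, not
counts of underlying events.

Map distances use the Perkins tetrad estimator per interval,

    X = 100 · (TT/2 + 3·NPD) / n  [cM],

with TT the classes whose pattern shows a single crossover in the interval
and NPD the classes showing a within-interval double (interval 1:
TT = {C,D,E,F,G,J}, NPD = {I,K,L}; interval 2: TT = {B,D,E,F,G,K},
NPD = {H,J,L}). The standard error comes from the multinomial delta method
on the (TT, NPD) proportions,

    SE = 100 · sqrt[(p_T(1−p_T)/4 + 9 p_N(1−p_N) − 3 p_T p_N)/n],

and distances are compared with a two-sided z-test on pooled SEs. The
reference implementation used historically for these tests is a calculator
without a published formula, so our SE is documented here as the package's
definition; on the published wild-type counts it gives p-values agreeing
with the published ones to within ~35% (e.g. 3.5 × 10⁻⁹ vs 5.2 × 10⁻⁹ for
the interval-1 wild-type/heterozygote contrast).

Interference is quantified by the ratio of the test interval's Perkins
distance among tetrads *with* a crossover in the adjacent interval to the
distance among tetrads *without* (strata: without = classes with PD in the
condition interval; the same TT/NPD mapping is applied within each
stratum). Ratios near 0 indicate strong interference, near 1 none. Ratio
differences between genotypes are tested by a seeded multinomial bootstrap
under the pooled null (default 10,000 resamples; resamples with empty or
zero-distance strata are dropped and an error is raised if they exceed
10%) — an explicit approximation, since no closed-form test is established
for this statistic.

This mapping reproduces every derivable published value of the three-color
table we target, including both stratified wild-type and heterozygote
distances and both interference ratios. Three published homozygote entries
(interval-1 distance 7.02, with-adjacent 8.26, ratio 1.24) are not
reproducible under any single consistent class→TT/NPD mapping we found
(the consistent mapping yields 7.25, 12.93 and 1.86 on those counts); we
report the consistent-mapping values rather than special-casing, and note
that the qualitative conclusion — ratio ≥ 1, no detectable interference —
is unchanged.

## Cis double crossovers and the matched-random null

Only phase-certain double crossovers enter the spacing analysis: block
triples homozygote–HET–homozygote with *equal* flanking states, which must
derive from two crossovers of one meiosis. Every such triple is reported,
including overlapping triples along a chromosome. Spacing is
midpoint-to-midpoint. The null reproduces the published control: for each
observed DCO, two intervals with the observed crossover-interval widths are
placed independently and uniformly on the same chromosome (non-overlap
enforced by rejection), and the spacing test is a two-sided
Mann–Whitney–Wilcoxon (normal approximation with tie correction) with the
direction of the median difference reported; a one-sided option exists.

A calibration caveat that users should understand: observed cis-DCO
spacings are *consecutive*-crossover gaps, while the null places two
*independent* uniform points. The two distributions coincide exactly when
the DCO-bearing chromosome carries only those two crossovers; whenever
gametes carry three or more, consecutive gaps are stochastically smaller
than the independent-uniform spacing, biasing the two-sided test toward
rejection with direction −1 even without interference. In our simulations
this is negligible at sparse maps (≲ 0.5 crossovers per gamete per
chromosome) but substantial at a 4-Morgan, 5-chromosome genome (~1 per
gamete per chromosome), where the type-I rate of the two-sided test at
gamma shape 1 reaches ~0.8; restricting to DCOs from exactly-three-block
chromosomes restores the nominal rate (measured 0.03 over 60 replicates).
The reported direction separates the phenomena: genuine interference gives
wider-than-random spacing (+1), the density artifact narrower (−1).
Interference detection at shape 5 on such dense maps has measured power
0.80 at p < 0.01 with ~85 DCOs (100 replicates).

## The meiosis simulator

Crossovers on a bivalent follow a stationary gamma renewal process on the
*genetic* axis: inter-event distances are gamma with shape ν and rate 2ν
per Morgan, so the event count has mean 2 × map length for every ν; ν = 1
is Poisson (no interference) and larger ν gives progressively regular
spacing. Stationarity uses the equilibrium forward-recurrence first draw —
for integer ν the exact Erlang mixture (gamma(k, rate), k uniform on 1..ν),
otherwise numerical inversion of the equilibrium CDF
F_e(x) = (rate/ν)·x·(1 − G_ν(x)) + G_{ν+1}(x) by Brent's method. An
obligate-crossover option resamples empty bivalents rather than forcing an
event, preserving conditional inter-event distributions.

Physical positions come from inverting a piecewise-constant cumulative
intensity (cM/Mb), which cleanly separates interference (ν) from landscape
(intensity) — the two axes the analyses probe. The telomere-biased
landscape multiplies the intensity in the terminal zone (default 1 Mb) and
rescales to a fixed total map length, so landscape comparisons are not
confounded by map-length changes.

Each crossover involves one of the two chromatids of each homolog chosen
uniformly and independently (no chromatid interference). The four gametes
are traced through the exchanges following original chromatid identity;
enumeration tests confirm the exact single-crossover anatomy (2 of 4
recombinant) and the 1:2:1 PD:TT:NPD distribution for two crossovers. An F2
individual is the marker-wise sum of one gamete from each of two
independent meioses (0 → P1, 1 → HET, 2 → P2), with blocks merged over
equal-genotype marker runs — so block boundaries sit at marker positions,
exactly as in sliding-window genotyping output. The default marker grid is
100 kb, a typical effective resolution for shallow genotyping-by-sequencing
block calls; finer grids change only boundary precision. The default study
configuration is 150 individuals on a five-chromosome, ~119-Mb layout with
a 4-Morgan map.

What the generator does *not* emulate: sequence-level reads and SNP
ascertainment, genotyping error, segregation distortion, aneuploidy and
viability selection in axis mutants, and sex differences in recombination.
Passing tests therefore demonstrate correctness of the estimators and
tests under the stated model, not robustness to those real-data phenomena.

## Coverage profiling

Alignment filtering mirrors standard ChIP-seq practice for a
Bowtie2-like aligner: alignments with more than two mismatches are dropped;
a read is unique if it has no secondary-alignment score and MAPQ ≥ 42;
otherwise candidates with MAPQ ≥ 10 compete, the maximum MAPQ wins and ties
break by a seeded generator (reads with MAPQ in [10, 41] and no secondary
score are handled under this multi-mapping rule and logged); pairs with a
single surviving mate are discarded. Coverage is normalized by library sum
(reads-per-billion scaling; the scale cancels in ratios), windowed as plain
means with terminal partial windows averaged over their actual width, and
turned into log₂((ChIP + pc)/(input + pc)) with a default pseudocount of
1 normalized unit — zero-coverage windows therefore stay finite; the
pseudocount is recorded on the track. Gene metaprofiles split bodies into
proportional windows and 2-kb flanks into 20-bp windows, average
overlapping coverage per window with empty windows set to 0 (the "w0"
rule), and reverse minus-strand rows so all run TSS→TTS. Track agreement is
Spearman's rank correlation over windows whose centers fall in a region
set (all, arms, or pericentromeres from the genome layout).

## Known limitations

* The Perkins estimator truncates above two crossovers per interval, so it
  under-reports long intervals when interference is weak (≈ −0.6 cM at
  20 cM under Poisson); under realistic interference the bias is
  negligible. Parameter-recovery tests are run at shape 5 for this reason.
* The Malkova-style bootstrap and the Perkins SE are our documented
  definitions of procedures whose originals are not reproducibly specified.
* The matched-random DCO null is exact only in the sparse-crossover regime
  (see above); direction must be consulted before interpreting small
  p-values on dense maps.
* The simulator draws meioses independently; it does not model obligate
  crossover failure, univalents, or inter-chromosome interference.
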