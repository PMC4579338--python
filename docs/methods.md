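# Methods

## Signal model

A SNP array reports, per probe, the log2 total-intensity ratio (LRR, ~0 for
two copies) and the B-allele frequency (BAF, ~{0, ½, 1} for AA/AB/BB in
diploid cells).  A post-zygotic aberration present in a fraction *f* of the
sampled cells mixes aberrant and normal signal linearly in intensity space.
For a constitutionally heterozygous probe the expected allelic dosage gives

- GAIN (2→3 copies in carriers): Δ = (1+f)/(2+f) − ½, L = c·log₂((2+f)/2)
- DEL (2→1): Δ = 1/(2−f) − ½, L = c·log₂((2−f)/2)
- CNNLOH (2→2, one homolog duplicated, the other lost): Δ = f/2, L = 0

where Δ is the absolute BAF deviation from ½ (each heterozygous probe falls
on one of the two branches ½ ± Δ, phase unknown), L the expected LRR shift,
and *c* a dimensionless platform response factor.  Real Illumina LRR is
attenuated (c < 1); the default c = 1 is self-consistent for synthetic data
and configurable for real arrays.  The three inverse formulas
(f̂ = 4Δ/(1−2Δ), 4Δ/(1+2Δ), 2Δ) are exact; a split above 1/6 cannot arise
from a single-copy gain and is flagged as multi-copy amplification with f̂
clipped to 1.  Single-copy changes are assumed for GAIN/DEL throughout —
margin events are low-level gains and losses; amplification beyond one
copy is reported via the clip flag, not modelled.

## Quality control

Samples enter the analysis only with SNP call rate strictly above 0.98 and
LRR dispersion strictly below 0.2.  The dispersion statistic ("LogRdev" in
array-QC parlance; the vendor formula is not public) is implemented as the
standard deviation of median-centred autosomal LRR, with a first-difference
alternative (sd of successive differences / √2, `dev_method="diff"`) that
genuine long-range copy structure cannot inflate.  The global-sd default is
the transparent choice for arrays whose aberrations cover a small share of
the genome; the derivative form is appropriate when events span a large
fraction of the (possibly reduced) genome, as in some simulations.

## Segmentation

LRR (all probes) and the folded deviation b = |BAF − ½| (restricted to
probes called AB in the matched control — the informative set, which also
immunizes against germline runs of homozygosity) are segmented separately
per chromosome by recursive binary splitting: at each level the split
maximising the absolute two-sample z statistic of the child means (pooled
within-child variance) is accepted if its two-sided normal p-value is below
α = 5×10⁻⁹ and both children keep ≥ 10 probes.  Breaks are forced at
chromosome boundaries and at inter-probe gaps above 1 Mb (the platform
setting "max contiguous probe spacing 500–1000" has unspecified units; it
is interpreted as a kb-scale gap bound and exposed as a configurable
`max_gap` in bp).  Ties go to the leftmost index; the procedure is fully
deterministic and, by construction, identical to a naive exhaustive
evaluation of every candidate split at every level — the test suite checks
this equivalence against an independent brute-force implementation.
α is applied per split, genome-wide, unadjusted (it is already extreme).

The two breakpoint sets are pooled per chromosome.  Where pooled breaks
fall closer than the minimum segment size (the two evidence channels
localising the same physical boundary), the leftmost is kept; forced gap
breaks are always kept.  Segments tile each chromosome; per-segment
statistics include mean LRR, informative-probe count, mean mirrored BAF
(½ + mean b), second moments of b for test and control, and the fraction of
informative probes pushed to the homozygous rails (BAF ≥ 0.95 or ≤ 0.05).

Numerical guard: child-mean differences at or below 10⁻⁹ are treated as
identical.  Noise-free synthetic data can otherwise produce "significant"
splits from float rounding (the two folded BAF branches of one event differ
by an ulp), since the pooled variance collapses faster than the mean gap.

## Calling

A segment is *imbalanced* when either (a) its mean mirrored BAF exceeds
1 − 0.46 = 0.54 (the heterozygous-imbalance threshold on the mirrored
scale), or (b) the paired z statistic

  z = (mean b_test − mean b_control) / sqrt((sd²_test + sd²_control)/n)

over the segment's informative probes reaches 5.  Folded noisy BAF has a
null mean of about ½ + σ√(2/π), not ½, so a one-sample test against ½ would
flag every clean segment; comparing test against control over the identical
probe set cancels the folding bias exactly, with no noise model.  Rule (b)
is what admits large, low-fraction events whose split is far below the 0.54
bound but precisely measured (a 50-Mb CNNLOH at 5 % of cells gives z ≈ 20
at default noise).  Segments with fewer than 10 informative probes are
never imbalanced ("uninformative" flag).

Imbalanced segments are classified by mean LRR: GAIN ≥ +0.05, DEL ≤ −0.05,
CNNLOH in between.  The ±0.05 neutral band is ≈ 3× the LRR standard error
of a minimum-size segment at default noise; the platform settings offer no
numeric band.  A non-imbalanced segment with ≥ 85 % of informative probes
at the homozygous rails and neutral LRR is scored CNNLOH with a "hom-run"
flag (constitutional-LOH runs where the split signal itself is saturated
or absent).

Candidate boundaries are then re-localized by a matched-filter edge scan in
a ±150-probe window: the signed difference of flanking-window means of the
informative signal (LRR for GAIN/DEL, folded BAF for CNNLOH) is maximised.
This repairs the few-tens-of-probes slack that pooling two independently
segmented channels can leave at one physical boundary.  Adjacent same-class
segments separated only by forced gaps are merged; segment statistics are
recombined from sufficient sums.

Δ is estimated per call as sqrt(max(0, E[b²]_test − E[b²]_control)) over
the call's informative probes.  Under symmetric noise E[b²] = Δ² + σ², so
the estimator is unbiased where the folded *mean* is not; this matters
precisely at low f, where the folded-mean bias would inflate f̂ by ~0.03.
The cell fraction f̂ comes from the exact inverse formulas (BAF is the
primary estimator; the LRR-implied fraction is reported as a consistency
column, `lrr_fraction`).  Calls carry machine flags instead of manual
curation: "clipped", "hom-run", "uninformative", and "low-confidence"
(z < 10 or < 20 probes); no call is silently removed.

Paired scoring: candidates are computed for the test sample and,
independently, for the control against itself (where germline events —
constitutional, Δ = 1/6 or ½ — are caught by rule (a)); any test candidate
matching a control candidate with the same class and reciprocal overlap
≥ 0.5 is removed.  Calling a control against itself yields zero calls, so
the subtraction is idempotent by construction.  The minimum reportable
event size is implied by min_probes × spacing, not a bp cutoff.

## Aberration load and strata

Per-sample load is the summed size (Mb, 1 Mb = 10⁶ bp) of scored calls
after merging overlapping same-class intervals, making it invariant to call
order and to splitting calls into adjacent pieces.  Strata: LOW below
105.6 Mb (strict), TUMOR_LIKE above 39 % of the genome (strict), else
INTERMEDIATE.  The genome denominator defaults to 3300 Mb, chosen so that a
1288-Mb load sits at the 39 % boundary (1288/0.39 ≈ 3.3 Gb; the exact
denominator behind the percentage convention is not derivable from
autosomal length alone, so it is configurable rather than resolved).
Chromosome X is excluded from load by default (all-female cohort design)
and can be included with `include_x`.

## Recurrence and cohort statistics

For one class, each subject contributes the union of its call intervals
(a subject counts once per base however many of its margins are affected;
per-sample counting is available via `by="sample"`).  The per-base
subject-count step function is built by an interval sweep; a *peak* is a
local-maximum plateau of that track — the smallest overlap of the calls
covering the most frequently affected locus.  Adjacent equal-count plateaus
separated by lower troughs are distinct peaks; where the contributing
subject set changes within a winning plateau, one peak per constant-set
atom is reported so that every peak interval is contained in every
contributing subject's covering call.  Frequencies divide by a cohort
denominator, by convention the number of subjects carrying at least one
scored call (configurable).  A per-base brute-force counter in the test
suite checks the sweep exactly.

Receptor-gene co-occurrence uses a bundled GRCh37 table of six
membrane-receptor genes (ERBB2, EGFR, FGFR1, IGF1R, LIFR, NGFR); a gene is
"gained" in a subject when any GAIN call overlaps it by ≥ 1 bp (no overlap
fraction is imposed).  Propagation matching pairs each margin call with
same-subject, same-class tumor calls at reciprocal overlap ≥ 0.5 and
reports f̂(PT) − f̂(UM).  The sampling statistic groups subjects by the
number of margins sampled and correlates that count with the group mean of
aberrant-margin counts (Pearson r; degenerate variance reported as
not-available, never 0).  The distance statistic is an ordinary
least-squares fit of load on edge-to-edge margin-to-tumor distance, with
margins carrying tumor cells at the sampling site entered at distance 0 and
multifocal subjects measured to the closest tumor.

## Synthetic cohorts

The generator emulates the paired study design: per subject one control,
1–3 margins, 1–3 tumor foci; germline genotypes drawn once per subject
under Hardy–Weinberg proportions from per-probe population allele
frequencies ~ U(0.05, 0.95) and shared across the subject's samples.
Defaults are the study conditions: 4-kb probe spacing (OmniExpress-class
density, ~770k probes genome-wide on the bundled GRCh37-like genome), LRR
sd 0.15, het-BAF sd 0.03, hom-BAF sd 0.01, missing-genotype rate 0.5 %.
Somatic events are placed uniformly (length-weighted chromosome choice,
log-uniform sizes, default 0.5–50 Mb), gains predominating (70/15/15 class
mix) with carrier fractions U(0.05, 0.9); margin events reappear in each
tumor focus with probability 0.9 at a strictly higher fraction
f_PT = f + (1−f)·U(0.3, 0.7).  Germline CNVs are constitutional (f = 1) and
identical across a subject's samples.  Multiple specs with different f in
one sample model clone heterogeneity.  Branch assignment for heterozygous
probes is an independent fair coin per probe.

One global seed is expanded into per-sample generators by hashing subject
and sample ids (CRC-32) into a `numpy` `SeedSequence`, so output is
byte-identical across runs and stable under subject reordering.

What the generator does **not** emulate — and hence what passing tests do
not establish for real arrays: GC waves and batch effects, attenuated and
heteroscedastic LRR, BAF asymmetry near the rails, genotyping-error
structure, probe-density variation, centromere/telomere gaps, and truly
subclonal nested events.  Results on synthetic data bound the method's
statistical behaviour under its own model, not platform artifacts.

## Problem sizes and verification

The test suite and the acceptance script use reduced genomes — one to three
chromosomes of 100–180 Mb at the unchanged 4-kb density and default noise —
sized so the full suite runs in a few minutes: sensitivity uses a
two-chromosome genome with a 50-Mb CNNLOH (50 replicates per fraction on
the {2,3,4,5,7,10} % grid), parameter recovery a 120-Mb chromosome with
30-Mb events (3 classes × 9 fractions × 20 replicates), and the
false-positive check 20 aberration-free paired samples.  Boundary accuracy
is asserted on the mean absolute boundary error (≤ 5 probe spacings for
f ≥ 0.2): at f = 0.2 the per-probe signal-to-noise is ≈ 1 and changepoint
errors have a heavy-enough tail that a hard maximum over hundreds of
boundaries is not a meaningful criterion, while the mean is stable (≈ 3
spacings).

## Known limitations

- No joint purity/ploidy fitting; f̂ assumes one event per segment over a
  diploid background (no multi-allelic or nested subclonal models).
- Breakpoints are probe-resolution; no bp-level refinement.
- The paired z (rule b) assumes test and control share their BAF noise
  scale; strongly discordant sample quality would bias it (QC bounds this).
- The control-subtraction match is interval-based (reciprocal overlap
  0.5, same class); pathological germline/somatic coincidences at the same
  locus with different classes are scored as somatic.
- Whether the vendor pooled LRR/BAF evidence before or after segmentation
  is unknown; here they are segmented separately and pooled after, with
  boundary refinement compensating.
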