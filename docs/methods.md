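# Methods

## Telomeric content (TRPM / TERRA)

A read is classified as telomeric when a single left-to-right greedy scan
finds at least `repeat_threshold` (default 7, appropriate for 49 bp
paired-end reads) non-overlapping occurrences of the common telomeric
hexamers TTAGGG, TCAGGG, TGAGGG, TTGGGG. Reverse-complement patterns are
matched by default because reads from aligned libraries occur on both
strands; the toggle exists for strand-resolved input. Matching is greedy
and non-overlapping (after a match the scan jumps six bases) because that
is deterministic and counts tandem repeat copies the way repeat-content
tools do; occurrences of different repeat types accumulate into one total.

Per-sample telomeric content is

    TRPM = n_telomeric / n_gc_matched x 10^6,

where `n_gc_matched` counts **all** reads whose GC fraction lies in the
inclusive window [0.48, 0.52] — including telomeric reads that land there.
The window bounds are inclusive by choice (a printed range "48–52%" does
not state openness). GC fraction is (G+C)/(non-N bases); N bases never
match a pattern and are excluded from both GC numerator and denominator so
clipped or masked reads are not penalised; an all-N read is excluded from
GC matching entirely. Mates of a pair are counted as independent reads —
the normalisation is per read, not per fragment. No duplicate removal is
performed.

When no read falls in the GC window, TRPM is reported as an explicit NA
rather than 0 or an exception: "no data" and "no telomeres" are different
findings. An optional linear rescaling of the threshold for non-49 bp
reads (`scale_threshold_by_length`, rounded, floor 1) is provided as an
extension and off by default.

TERRA content applies the identical counting rule to RNA reads and is kept
as a separate entry point only so DNA and RNA results are labelled
distinctly in outputs.

The production path is a vectorised batch engine (byte-matrix pattern
matching with a pointer-advance greedy scan across all reads at once); the
scalar per-read functions define the semantics, and the test suite asserts
scalar/batch equality and equality with an independent brute-force
scanner.

## Enrichment screen

Within each disease group with at least `min_group_size` samples (default
40, mirroring the restriction of the source analyses to disease groups
with more than 40 samples), samples are dichotomised by TRPM quartile:
high iff TRPM >= Q3, low iff TRPM <= Q1, middle otherwise. Q1/Q3 use the
linear-interpolation quantile definition. A sample qualifying as both
(possible only when Q1 = Q3) becomes middle, so a fully degenerate group
produces no high/low labels and is skipped with a logged reason. Since the
labels depend only on ranks, dichotomisation is invariant to strictly
monotone transforms of TRPM.

Each (feature, disease) pair is tested with a two-sided Fisher's exact
test on the 2x2 table altered/WT x high/low. "Altered" means known or
likely pathogenic; variants of unknown significance sit in the WT stratum
by construction of the input. The reported odds ratio is the sample
cross-product ad/bc (+inf when bc = 0 and ad > 0; undefined for 0/0), not
the conditional MLE; no continuity correction is applied. Sidedness is
two-sided with direction enforced downstream by the OR > 1 filter.

Bonferroni correction spans all tests actually performed (global family,
the conservative reading); a per-disease family is available by
configuration. A **screen hit** is a feature with adjusted p < alpha
(default 0.05) and OR > 1 in at least `min_diseases` (default 2) distinct
disease groups.

The band-level screen applies the same machinery to an ordered list of
cytobands pooled across the cohort. The comparator defaults to the bottom
quartile, consistent with the gene screen; a top-quartile-vs-rest mode is
provided because the band analysis could also be read that way. The
**minimal region** is the maximal run of consecutive bands with adjusted
p < alpha and OR > 1, ties between equal-length runs broken by the
smaller minimum adjusted p.

## Band calls

Copy-number segments are intersected with a cytoband table (0-based
half-open everywhere internally; readers convert 1-based inclusive input
behind an explicit flag). A band is called amplified when at least 1 bp of
an amplified segment overlaps it — amplicon boundaries are imprecise, so
requiring a larger overlap is left as a configuration. The cytoband table
is always an input, never embedded: band definitions are a property of the
genome release in use.

## Group statistics

*Wilcoxon rank-sum*: midranks for ties; exact enumeration when both
samples have n <= 10 without ties, otherwise the normal approximation with
tie and continuity corrections.

*Dunn's test*: joint midranks over all values; for a pair (i, j),
z = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))] (1/n_i + 1/n_j)),
two-sided p from the standard normal. On tie-free two-group data this
reduces algebraically to the Wilcoxon normal approximation without
continuity correction, which the tests verify to 1e-10 relative
tolerance. Bonferroni counts only the comparisons reported — all pairs,
or only pairs against a designated reference group (e.g. WT) when given.

*Combination groups*: each sample is labelled by its altered genes
("RAD21+/TERC+", "WT", ...); combinations with fewer than 5 samples are
dropped rather than pooled, since only populated combinations are
interpretable.

*Mutual exclusivity*: the statistic is coverage — the number of samples
with at least one alteration among the tested genes — which is maximal
under exclusivity. The null permutes each gene's column independently,
preserving per-gene frequencies; p = (1 + #{perm >= obs})/(n_perm + 1).
This is a deliberate methodological substitution for likelihood-ratio
mixture approaches: the qualitative property (alterations in genes serving
the same pathway avoid co-occurring) is testable either way, and the
permutation test is assumption-free and exactly valid. Note the exact
permutation p of a discrete statistic is *super-uniform* under the null
(P(p <= a) <= a); its null distribution approaches the continuous uniform
only when the coverage statistic has many attainable values, i.e. at
cohort sizes in the thousands for two genes. Calibration checks are run at
n = 2000 for that reason.

## Survival

Left truncation: a subject is at risk only strictly after their entry
time, so the risk set at t is {entry < t <= exit}. Censored exits shape
risk sets only. Ties between deaths and censorings at the same time
resolve with deaths first (the standard convention), which this risk-set
definition encodes automatically. With all entries zero the estimator is
exactly the classical product-limit KM (verified against an independent
implementation and against lifelines with entry times).

Under heavy truncation a risk set can be empty at an event time; the curve
is then flagged unstable from that time and held constant rather than
raising.

Median survival is the smallest event time with S(t) <= 0.5 (undefined
when S plateaus above 0.5). Its confidence interval follows the
Brookmeyer–Crowley idea on the log scale: pointwise bands
S exp(± z se_logS) with the Greenwood variance, and the median CI bounds
are the first crossings of 0.5 by the lower/upper bands. This is a
documented choice; other CI constructions exist.

The log-rank test uses the same truncated risk sets: U = Σ(d_a − e_a),
V = Σ hypergeometric variances, χ² = U²/V against χ²(1).

## Synthetic data: what it emulates, and what it does not

*Reads* (`gen_reads`): telomeric reads are hexamer concatenations drawn
from a mixture (default 0.91/0.03/0.03/0.03 — the canonical TTAGGG
dominates real telomeres, variants are minority), truncated to the read
length (default 49 bp), reverse complemented with probability 0.5
*after* truncation (so GC is preserved exactly, which the closed-form
expectation exploits), then point-mutated uniformly. Background reads are
i.i.d. bases at a controllable GC. `expected_trpm` gives the exact
expected TRPM for error-free simulations: the telomeric GC count is
3·full + Binomial(full, w_variant) plus a small prefix term, and the
background window probability is a Binomial tail; the SE comes from the
multinomial delta method over the four read categories. Not emulated:
quality profiles, indels, adapter content, coverage structure,
subtelomeric sequence.

*Cohorts* (`gen_cohort`): TRPM is log-normal per disease (median 1200,
sigma 0.8 on the natural log — telomeric content distributions are
right-skewed on a positive scale, and this spread matches the
interquartile ranges such cohorts display). Alteration effects are
multiplicative on TRPM, hence additive on the log scale, so co-occurring
alterations combine additively — the structure the
combination-group analysis is designed to detect. Alterations are
independent Bernoulli draws (default frequency 0.10) except within an
optional exclusivity group, where at most one gene per sample is altered.

*Segments* (`gen_segments`): carriers (default 5% of samples) receive one
amplicon covering a causal 5-band interval, overhanging into each flank
with probability 0.8 and continuing outward geometrically (0.3) — the
band adjacent to the causal region is therefore co-amplified in ~80% of
carriers, as a neighbouring oncogene riding the same amplicon would be.
Independently, any sample may receive a focal passenger amplicon per side
(rate 0.5) anchored at the adjacent band and extending away from the
causal interval, with no TRPM effect — the frequent oncogene-anchored /
arm-level gains that, in real cohorts, dilute the flank's marginal
association toward the null. This dilution is not decoration: without it,
flank amplification would *imply* carrier status and hence high TRPM, and
no analysis could statistically separate the flank from the causal run.
The default rates were fixed by a design power analysis (carrier
enrichment in the top quartile vs the flank's diluted contrast under
Bonferroni across 15 bands at n = 800) before any acceptance measurement,
and give ~95% exact-recovery probability. Passing tests show the screen
separates a causal interval from correlated passengers *under this
dilution structure*; they do not show robustness to amplicon landscapes
with no independent flank amplification, where the separation is
information-theoretically impossible.

*Survival* (`gen_survival`): exponential event times per group (defaults:
medians 10 vs 14.5 months for altered vs wild-type, group sizes 240/924 —
a realistic altered-minority clinical cohort), uniform entry times on
[0, 6] months, exponential censoring of post-entry follow-up (60-month
half-life). Sampling is rejection-based: subjects whose event precedes
their entry never appear, which is precisely the left-truncation
mechanism the estimators must undo.

## Numerical and procedural choices

- Quantiles: linear interpolation between order statistics.
- Fisher p: two-sided hypergeometric sum of tables no more probable than
  the observed one (scipy); verified against an integer-exact enumerator
  for every table with N <= 40 (agreement to ~4e-16).
- Bonferroni adjusted p is clipped at 1; significance is strict (<).
- Undefined TRPM records are excluded before dichotomisation, with a
  logged count; disease skips are reported, never silent.
- All generators take mandatory seeds; the pipeline derives per-stage
  seeds from one master seed via `SeedSequence.spawn`, making reruns
  byte-identical.
- Problem sizes in the test-suite simulations (e.g. 500 null cohorts of
  8x200 samples, 100 recovery replicates at n = 800, 2,000 log-rank null
  replicates) were chosen as the smallest sizes at which the Monte-Carlo
  error of each check is comfortably below the property being asserted.

## Known limitations

- The repeat scanner counts fixed hexamers only; degenerate or divergent
  telomeric repeats are not matched.
- The screen is marginal (no covariate adjustment, no logistic model);
  only Bonferroni is offered because the downstream hit filter is designed
  around family-wise control.
- The mutual-exclusivity test conditions on per-gene frequencies but not
  on per-sample mutation burden; burden heterogeneity can inflate
  coverage-based exclusivity signals in real data.
- Median-survival CIs use one particular (log-scale Greenwood) band
  construction.
- Synthetic generators are stylised; see above for the specific realism
  gaps per generator.
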