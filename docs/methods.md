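# Methods

## Scope and model

`m5cpipe` implements the computational core of transcriptome-wide m⁵C
mapping by RNA bisulfite sequencing (bsRNA-seq).  Bisulfite deaminates
unmethylated cytosine to uracil (sequenced as T) while 5-methylcytosine
resists conversion, so the fraction of reads retaining C at a cytosine — the
*non-conversion ratio* — estimates the methylation stoichiometry of that
position.  The pipeline covers four stages:

1. **conversion counting** — strand-aware per-cytosine tallies of
   non-converted / converted / other bases from alignments, with read-level
   quality masking and the 3C artifact filter;
2. **site calling** — a cascade of inclusive thresholds per replicate plus a
   replicate-integration rule, union merging across samples, and a decision
   tree explaining site sharing between sample pairs;
3. **writer assignment** — NSUN-enzyme dependence from depletion and
   overexpression contrasts, 6-position PWMs trained on dependent-site
   contexts, log-odds scanning with exact match p-values, and corroboration
   by base-pairing propensity and methylation–expression correlation;
4. **spatial analyses** — metagene densities with background-cytosine
   controls, codon-anchored chi-squared enrichment, and Fisher-exact
   co-enrichment of sites with RBP eCLIP footprints, BH-adjusted across
   RBPs.

A synthetic-data generator produces ground-truthed transcriptomes,
methylomes, pileup evidence, depletion conditions and footprints with the
statistical structure these analyses assume, so every stage can be validated
against known truth.

## Evidence model and filters

Counts are kept raw and post-3C.  A read with more than three non-converted
cytosines is treated as a conversion failure (typically structure-protected
RNA) and removed; the signal-to-noise ratio of a position is the fraction of
its reads surviving this filter.  A cytosine passes in one replicate iff,
after the 3C filter:

* S/N ≥ 0.9, total coverage ≥ 20 ("20RC"), non-converted reads ≥ 3,
  C+T fraction of coverage ≥ 0.8 ("80CT"), and non-conversion ratio ≥ 0.10
  ("10MM") — all boundaries inclusive.

The non-conversion ratio uses C+T coverage as denominator; other bases are
a separate contamination signal caught by 80CT.  A site is called when ≥ 2
replicates pass, or exactly one passes with ≥ 5 non-converted reads.  The
reported level pools non-converted over C+T coverage across passing
replicates (a pooling rule had to be fixed; pooling weights replicates by
their coverage).  The 10% ratio is evaluated on post-3C counts, matching the
filter order (3C first).  All coordinates are 0-based half-open internally.

Alignment parsing masks bases under Phred 30 and trims 6 nt from *both*
read ends (whether one or both ends should be trimmed is ambiguous;
trimming both is the conservative reading and is configurable).  Uniquely
mapped means MAPQ above a configurable floor with secondary/supplementary
alignments excluded.  Overlapping paired-end mates are counted once with
first-mate precedence.  Precomputed count tables can be supplied directly,
in which case the quality rules are assumed already applied.

## Dependence rules and PWMs

Loss contrasts (NSUN2/NSUN6 knockout or knockdown): a site is dependent iff
its level drops by **more than** 0.05 *and* the residual level is **below**
0.10.  Gain contrasts (NSUN5 overexpression): dependent iff the level rises
by **at least** 0.05 to **above** 0.10.  Comparisons carry a 1e-9 guard so
levels compared at printed (two-decimal) precision behave exactly at the
boundaries.  Sites with coverage under 20 in either condition are
uninformative.  Verdicts from independent depletion datasets combine by
logical OR.

PWMs are position probability matrices over {A,C,G,U} × offsets 0..+5 (the
site C at offset 0), smoothed with pseudocount 0.25 per base (prevents −∞
log-odds; the value is conventional additive smoothing).  Scanning scores
the anchored 6-mer by log₂ likelihood ratio against the background
composition and converts it to an exact match p-value by enumerating all
4⁶ = 4096 background 6-mers.  The default significance threshold is
**p < 0.01**: with only six positions the null p-value is a step function
whose minimum is 4⁻⁶ ≈ 2.4 × 10⁻⁴ under a uniform background, so thresholds
in the 10⁻⁴ range used by genome-scale motif scanners are unattainable and
would label every site "other"; 0.01 admits near-consensus matches while
claiming ≲ 2–4% of random contexts.  The best-scoring enzyme whose match
p-value passes wins; an exact score tie or no qualifying match yields
"other"; sites within 5 nt of the transcript 3′ end are uninformative.
NSUN5 is identified by the gain contrast, not by a PWM — its extended
GUNGCCANNUG context is longer than the scanned window.

Base-pairing propensity uses a deterministic maximum base-pairing
(Nussinov-style) fold — Watson–Crick plus G:U, minimum hairpin loop 3 —
on ±50 nt windows, reporting the fraction of sequences in which each offset
is paired; a matched profile from sampled unmethylated cytosines serves as
background.  The engine is pluggable so a thermodynamic folder can be
substituted; maximum pairing is sufficient for the coarse paired/unpaired
meta-profile and is exactly reproducible.

Methylation–expression correlation includes a site iff its coverage exceeds
20 in at least five samples and computes Pearson r over exactly those
samples; zero-variance vectors yield missing values.

## Metagene and RBP analyses

Metagene coordinates concatenate 5′UTR/CDS/3′UTR after scaling each region
to its mean length over the site-bearing transcripts (explicit means such as
270/2058/1817 nt can be supplied to reproduce published axes).  The
fractional position within a region is `(pos − start) / (len − 1)`, a
closed-interval convention under which the first transcript nt maps to 0 and
the last 3′UTR nt to the full scaled length.  Annotation reports all
overlapping features but labels each site by the priority
5′UTR > CDS > 3′UTR > ncRNA_exonic > intronic > intergenic; per gene the
longest coding transcript containing the site is used.  Densities are
histograms normalised to unit mass with identical binning for sites and
background; codon-anchored enrichment uses ±300 nt in 50-nt bins (the bin
width is a package default, chosen to resolve the ~100-nt scale of
codon-proximal structure while keeping ≥ 20 background counts per bin in
typical data) with per-bin 2×2 Pearson chi-squared (no continuity
correction).

RBP footprints are retained when replicate intervals overlap and both carry
fold-enrichment ≥ 4 and p ≤ 10⁻³; the intersected interval is kept with the
weaker replicate's evidence and anchored at its midpoint (left-median for
even widths).  Enrichment restricts to genes carrying both a footprint and
an m⁵C site, flattens overlapping ±w windows so no cytosine is counted
twice, and Fisher-tests sites vs background cytosines inside/outside the
windows (two-sided; chi-squared is also reported).  Background counts use
all annotated cytosines of qualifying transcripts, not only covered ones —
an assumption, since coverage-conditional backgrounds would couple the test
to sequencing depth.  Offsets are mature-mRNA (spliced) coordinates.
BH-FDR is applied across RBPs.  The five-category transcriptome grouping
(neither / site only / footprint only / both-distal / both within ±50 nt)
partitions every gene exactly once, and group shifts on an external
differential-expression table use Welch's unequal-variance t-test, skipping
categories with fewer than three genes.

## Synthetic-data generator

The generator emulates: transcript architecture with region lengths
gamma-distributed (shape 4, CV 0.5) around means 270/2058/1817 nt;
over-dispersed coverage, negative binomial with mean 50 and dispersion 0.5
(variance μ + 0.5μ²); a global conversion-failure rate of 0.003 (matching
≥ 99.6–99.7% observed conversion); stoichiometries uniform on [0.10, 0.60]
to stress the 10% calling threshold, where real data concentrate; writer
proportions of roughly two-thirds NSUN2, one-sixth NSUN6 and one-sixth
unattributed; and writer-specific contexts — NSUN2 sites receive a 3′
G-rich tract (each of offsets +1..+5 is G with probability 0.9, mimicking
the tRNA variable-loop context), NSUN6 sites CUCCA at 0..+4, NSUN5 sites
GUNGCCANNUG with the modified C at the fifth base.  Sites keep ≥ 12 nt
spacing so contexts cannot overwrite each other.

Non-artifact evidence is count-level under an equivalent-read expansion
(each coverage unit is one read observing one cytosine and always passes
the 3C filter); non-converted counts are Binomial(coverage, stoichiometry)
at sites and Binomial(coverage, failure rate) elsewhere.  Structure
artifacts are emitted as explicit read records — each covering five
consecutive cytosines with the first four non-converted — because the 3C
and S/N filters are read-level; their contributions are added to the raw
counts and removed again by the 3C filter.  The artifact fraction defaults
to 0.005 of reads: sparse enough that S/N stays above 0.9 at most
positions, as the S/N filter presupposes, while still exercising both
read-level filters.  Depletion multiplies the stoichiometry of one writer's
sites by a residual factor (capped at 1; factors > 1 model
overexpression gain).  Footprints for an enriched RBP centre within ±50 nt
of a random true site with configurable probability (default 0.8) and
uniformly otherwise; two pseudo-replicates carry jittered boundaries and
sampled fold-enrichment/p-value columns so peak filtering is exercised.

What the generator does **not** emulate: FASTQ-level reads, alignment and
mapping error; non-uniform site placement along transcripts (so no
codon-proximal clustering — metagene *mechanics* are validated, observed
enrichment patterns are not); sequence-composition bias; C→other
miscalls (the 80CT filter is exercised only by hand-built tables);
expression-coupled coverage between conditions.  Passing tests therefore
demonstrate correctness of the decision rules and calibration of the
statistics under the assumed evidence model, not robustness to artifacts
the model lacks.

## Numerical choices and validation conditions

* The noise-free recovery benchmark uses constant 1000× coverage with
  stoichiometries ≥ 0.15.  At the nominal 20-read floor, binomial sampling
  alone leaves a ~40% chance that a 15%-methylated site yields < 3
  non-converted reads, so exact recall/precision of 1 is only a property of
  the deep-coverage regime; the benchmark isolates rule correctness from
  sampling noise.
* Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  verifies them against an exact integer hypergeometric enumeration over
  every margin configuration up to 50, reduced to canonical representatives
  under the row/column-swap and transpose symmetries (with the invariance
  itself asserted on a sample).  BH q-values come from
  `statsmodels.multipletests` and are verified against a hand-rolled
  step-up.
* The null-calibration screen (footprints independent of sites, 1000
  simulated RBPs) and the power screen (0.8 placement enrichment vs null
  RBPs over 100 seeds) use 60 transcripts, 300 sites and 200 footprints
  per RBP, sizes at which the contingency tables are large enough for the
  exact test's discreteness not to distort its size; background cytosines
  are thinned 4× for speed, which leaves the test's margins in the
  thousands.
* PWM match p-values are exact (full 4⁶ enumeration); ties are included at
  a 10⁻⁹ score tolerance.
* Determinism: every stochastic routine takes a seed or NumPy generator;
  identical configurations produce byte-identical outputs.

## Known limitations

* Single-isoform metagene mapping: a site is profiled on one chosen
  transcript, not averaged over isoforms.
* The sample-pair binomial test is one-sided against the sample's global
  error rate with p < 0.05; the decision tree's boundaries (1% and 10%)
  are conventions carried over from the calling thresholds.
* `count_cytosines` expects mate 1 before mate 2 in file order when
  resolving paired-end overlap.
* The Nussinov engine maximises pair count and can over-pair relative to
  thermodynamic folds; profiles are comparative (site vs background), which
  absorbs most of this bias.
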