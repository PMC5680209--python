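# Methods

## Scope and data model

The unit of analysis is the deduplicated pileup: per genomic position, the
surviving read depth, the count of reads carrying one designated
alternative base, per-strand counts, and the 0-based offsets of the variant
base within its supporting reads. No FASTQ/BAM synthesis is attempted;
alignment, duplicate marking and base recalibration are treated as
upstream. Split-read records for fusion calling are likewise consumed as
structured records, not raw alignments.

## Synthetic data generator

The generator emulates clinical panel sequencing at the level the pipeline
consumes:

* **Depth** is negative-binomial around the target mean (panel coverage is
  overdispersed across capture targets); the dispersion (size) parameter
  defaults to 8, giving a coefficient of variation ≈ 37% at 1000×, and is
  raised in tests that need tighter coverage. Nominal depth is thinned
  binomially by a deduplication survival fraction (default 0.8, matching
  the ~800× effective vs ~1000× nominal coverage typical of FFPE panel
  libraries).
* **Alleles** are binomial at the effective depth. For somatic variants the
  success probability is the purity/clone/copy-state expectation
  P·c·Y / (P·c·X + 2P(1−c) + 2(1−P)) combined with the error term; for
  germline het SNPs the normal compartment contributes one alt allele of
  two, giving the purity-inference expectation below. Sequencing error uses
  a single global per-base rate ε = 0.001, split uniformly over the three
  non-reference bases; only the designated alternative base counts toward
  the alt tally. No base-context error profile is modeled.
* **Read offsets** are uniform on [0, 99] (100 bp reads); strand
  assignment is fair-coin per read.
* **In-silico dilution** converts each variant-supporting read to
  reference independently with probability 1 − f_target/f_observed, using
  the site's *observed* VAF as denominator — the realized concentration of
  a manual dilution differs from the nominal one, and anchoring on the
  observation avoids that bias. Downsampling is hypergeometric (without
  replacement); pool-level thinning in the dilution grid uses the same
  mechanism per site.
* **Normal cohorts** draw Hardy–Weinberg dosages Binomial(2, AF) per
  sample at injected population frequencies; exon depth matrices apply a
  shared per-exon capture-efficiency factor (log-normal, σ = 0.3) plus
  per-cell multiplicative noise of configurable CV; split-read generators
  emit configured side splits, mapping qualities, strands and
  secondary-alignment flags.

What the generator does **not** emulate: FFPE deamination and oxidative
artifact spectra, alignment error hot-spots, GC-dependent coverage trends
beyond the static per-exon factor, indels, and correlated errors across
nearby positions. Tests passing on this substrate therefore demonstrate
the *statistical* machinery (calibration, inversion, thresholds), not
robustness to every artifact class in real libraries; the artifact filter
is exercised on synthetic feature distributions, not real artifact data.

All generators are bit-reproducible given (config, seed); every CLI stage
echoes seed and configuration to a JSON manifest.

## Reference detection model

A site is called iff alt ≥ 4 and P(Binom(depth, ε/3) ≥ alt) < 10⁻⁶
(optionally also a VAF floor). The rule is deliberately minimal: a
transparent, fully specified stand-in whose LOD behavior can be derived
exactly, rather than a re-implementation of any production caller
composite. The three parameters are configuration, because any LOD claim
is conditional on the caller: production pipelines apply quality-,
alignment- and context-aware penalties that make them *less* sensitive at
very low VAF than this rule. Consequence: calibrated 95%-sensitivity
depths at 2% and 5% VAF come out near ~475× and ~160×, well below the
~1085×/294× that a two-caller clinical pipeline on real reads requires —
the machinery is the same, the operating point of the caller is not. At
10–40% VAF the depth requirements (~80×/37×/17×) are caller-insensitive
because they are dominated by the 4-read floor and binomial sampling.

## LOD calibration

Sensitivity is tallied per (VAF, depth) cell: each substrate SNP is
re-diluted per repetition (fresh conversion randomness), thinned to each
grid depth it can support, and re-detected. Trials are binned by
*realized* post-dilution VAF within ±20% relative width of the nominal
target; trials outside the bin are dropped, which keeps the "2%" curve
from being contaminated by sites that happened to dilute to 3%.

The probit model P(detect) = Φ(a + b·log₁₀ depth) is fitted by maximum
likelihood (binomial GLM with probit link). log₁₀ depth is used because
calibrated depths span two orders of magnitude (tens to >1000×). Fits with
b ≤ 0 are rejected for depth solving. Complete separation (every cell 0%
or 100%, split by a depth threshold) has no finite MLE; the fit then adds
half a success and half a failure per cell (Jeffreys-style bias reduction)
and is flagged. The 95% target follows the CLSI convention ("consistently
detected with ≥95% sensitivity") and is configurable.

`lod_at_depth` returns the smallest calibrated VAF whose 95% depth does
not exceed the queried depth — a discrete, conservative rule; queries
outside the calibrated range are flagged rather than silently
extrapolated. The per-position LOD report marks zero-depth positions "no
power" and positions whose LOD exceeds a configurable ceiling (default
50%) "insufficient power".

Default assay sizes: 222 substrate SNPs at ~1500× deduplicated coverage,
10 repetitions per cell, a 13-point geometric depth grid from 12× to the
substrate depth; four to five target VAFs from 2% to 40%. The whole
calibration runs in seconds on one core.

## Filtering and classification

Filters set independent flags (hence commute; a call survives iff no flag
is set):

* **Germline VAF**: VAF ≥ 0.97 removes, with hotspot positions exempt.
  The ≥ convention is used at the boundary. The rule is applied to raw
  (not purity-corrected) VAF.
* **Panel of normals**: cohort allele frequency > 0.03 removes (strict >
  at the boundary). "Population allele frequency" is the carrier-allele
  fraction Σdosage/(2N) — the standard convention; positions absent from
  the cohort count as frequency 0.
* **Blacklist**: exact (chrom, pos, ref, alt) membership.
* **Artifact model**: logistic regression on four features — indel within
  25 bp (indicator), count of other candidates within 50 bp, strand-bias
  score (−log₁₀ of the two-sided Fisher exact p on the 2×2 strand table),
  and read-position clustering 1/(1 + sd of alt read offsets). Window
  sizes and the clustering transform are package choices, configured and
  logged. The operating point is the maximal-Youden-index point of the
  ROC curve; AUC is reported by stratified cross-validation. Perfect or
  quasi-separation (training AUC of 1, or exploding weights) triggers an
  L2-regularized refit, flagged in the results. Training labels are the
  caller's responsibility (e.g. low-VAF calls in normal samples at
  positions with abnormally high transition/transversion rates — the
  cutoff defining "abnormally high" is exposed as a parameter, not
  hard-coded).

Tiers: 1 for positions on the actionable list, else 2 for known (COSMIC)
positions, else 3; fusions with a known partner gene are tier 1, novel
partners tier 2.

## Purity

Expected AAF of clustered germline het SNPs:
(P·Y + (1−P)) / (P·X + 2(1−P)); closed-form inverse
P = (2A − 1)/(Y − 1 − A(X − 2)), clipped to [0, 1]. Degenerate states
((2,1); (4,2)) have zero denominator and are skipped, as is the P = 0
root (AAF 1/2 is equally consistent with a plain het and carries no clone
evidence).

Copy-neutral anchoring: SNPs with AAF in [0.40, 0.60] enter a Gaussian
KDE of depth; the most prominent peak is the neutral coverage (rationale:
genome-wide 4N tumors are rare, so the dominant balanced-SNP coverage mode
is two-copy). Segments — one per input chromosome label; in practice the
contiguous panel segment is the clustering unit — are labeled gain/loss at
ratio > 1.10 / < 0.90 versus the peak. Fewer than 20 balanced SNPs, or no
prominent peak, declines estimation rather than guessing.

Because a germline het SNP places its alt allele on either haplotype, AAFs
inside a CNV segment are bimodal around 1/2; clusters therefore pool
*folded* AAF max(a, 1−a), depth-weighted. Folding is exact:
AAF(P, X, Y) = 1 − AAF(P, X, X−Y), so the folded hypothesis grid
{(1,1) loss, (2,2) neutral, (3,2), (4,3) gain} covers the full grid
{(1,0),(1,1),(2,2),(3,1),(3,2),(4,1),(4,3)}. Solutions whose implied AAF
misses the observation by more than 0.05 (possible only after clipping)
are discarded. Purity is the **maximum** surviving per-cluster P (largest
clone ≈ purity); estimates below 0.30 are kept internally but flagged
unreliable and withheld from reports.

Known limitation: (X, Y, P) is not identifiable from (AAF, coverage)
alone — e.g. (4,1) at P and (3,1) at 2P produce identical observations.
The max rule resolves such ties toward the lower-ploidy, larger-P
interpretation; recovery guarantees in the tests use unambiguous truth
states ((3,2) gains, (1,0)/(1,1) losses).

## CNV

R = (depth / sample mean target depth) / (median normalized depth of ≥ 3
normals at the exon); zero-median exons are masked. Implied copy number
C = max(0, (2R − 2(1−P))/P); amplitude log₂(C/2) (−∞ for C = 0, which
deletion calling handles naturally). Gene amplitude is the **median** exon
amplitude; calls use strict inequalities at ±1 log₂ (an amplitude of
exactly 1.0 is neutral). Log base 2, median aggregation and the strict
boundary are package choices, all configurable. Per-exon standardization
against the normal reference implicitly absorbs capture-efficiency and GC
effects; no explicit GC regression is fitted. Sample-level normalization
assumes CNV genes are a minority of the panel (true for multi-hundred-gene
designs); segmentation across genes and allele-specific copy number are
out of scope.

## Fusions

Split reads cluster when both alignment segments agree on chromosome and
lie within 10 bp of the cluster's modal coordinates (ties at the mode
break to the smaller coordinate). Per-read filters: MAPQ ≥ 20 and
matched (CIGAR M) length ≥ 20 bp on both segments; cluster filter: the
modal (strand_a, strand_b) pair must cover ≥ 80% of supporting reads.
The decision rule is ≥ 4 supporting split reads with ≥ 2 on each side;
primary and secondary alignments count equally. The numeric filter
thresholds are package defaults (the qualitative filter set — mapping
quality, segment description, strand concordance, cluster support — is
standard); all are configurable. Discordant-pair evidence and assembly
are not used.

## dPCR and summaries

λ = −ln(1 − k/n) from the Poisson zero term; saturated channels (k = n)
raise rather than report a pseudo-value. VAF = λ_mut/(λ_mut + λ_wt).
Droplet volume (default 0.85 nL, the common instrument value) is used only
for absolute concentration, never for VAF. Concordance between panel and
dPCR VAF estimates is the Pearson correlation, reported overall and by
depth tertiles. Cohort VAF summaries report the fraction of calls
*strictly below* each threshold (ties count as not-below), with counts
alongside; thresholds default to 5/10/20%.

## Numerical notes

* The binomial error test is evaluated as a per-depth minimal alt-read
  threshold (exact tail inversion with local adjustment), making grid
  detection vectorizable and exactly equivalent to the per-site test.
* Fisher exact p-values come from scipy; the test suite verifies them
  against an exhaustive hypergeometric enumeration for all tables with
  margins ≤ 30, and the probit depth solver against the exact smallest-
  depth binomial solution for "alt ≥ k" rules (within 10%).
* Probit CIs are Wald intervals from the GLM information matrix; the
  parameter-recovery tests check coverage over repetitions rather than a
  single draw.
* All stochastic stages take explicit integer seeds; seeds for internal
  sub-streams are derived with `numpy.random.SeedSequence`.
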