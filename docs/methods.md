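# Methods

This note documents the models, estimators and design choices behind
`editscan`, and what the synthetic-data experiments do and do not show.

## Coordinates and formats

All intervals are 1-based inclusive internally; BED conversion to
0-based half-open happens only in the writer/reader. The text-pileup
reader implements the legacy samtools base-string grammar (`.`/`,`
reference matches by strand, case-coded substitutions, `^X`/`$`
read-start/end marks, `+n`/`-n` indel attachments to the preceding
observation, `*` deletions, `>`/`<` reference skips); depth conservation
against the depth column is asserted per line. SAM I/O goes through
pysam/htslib; a record whose CIGAR does not consume exactly the query
length is rejected with a warning and the run continues. VCF 4.2 output
encodes each failed filter by name in FILTER and the DNA/RNA depths,
fractions and Fisher p in INFO.

## Editing-site calling

The caller treats editing as an RNA-unique allele against matched DNA:

* site gate: mean base quality ≥ 20 and coverage ≥ 6 in both materials
  (strict "below"/"less than" rejection, so boundary values pass);
* read-level filters, each an independent predicate on the fixed
  observations (so the PASS set is order-invariant): alt support at the
  first or last base of its read is discounted (a config switch
  `drop_variant_on_any_end_read` selects the stricter reading where any
  end-of-read support kills the variant — the default discounts
  observations and keeps the variant if internal support remains);
  single-strand alt support fails; alt support inside inserted/deleted
  segments is discounted, pileup-style (the anchor base preceding an
  indel run carries the context);
* calling thresholds: RNA coverage ≥ 8, variant fraction ≥ 0.05, ≥ 2
  clean supporting reads, DNA alt fraction ≤ 0.02, two-sided Fisher
  exact p ≤ 0.05 on [(dna_ref, dna_alt), (rna_ref, rna_alt)].

The DNA ceiling of 2% operationalizes "uniquely found in RNA": it
separates editing from heterozygous variants (≈ 50% in DNA) while
tolerating DNA sequencing error. The "high-confidence" notion of
somatic-caller post-processing is realized as the Fisher condition plus
the 2-read support floor rather than a bit-for-bit reproduction of any
specific caller's tier logic. No multiple-testing correction is applied
at the calling stage; recurrence across ≥ 2 samples (restricted to
non-synonymous changes when requested), HLA-gene exclusion, and
validation-cohort re-detection (alt fraction ≥ 0.05 at coverage ≥ 6 in
at least one sample) serve as the error control. VAFs are kept as exact
ratios until reporting (4 decimals in VCF INFO).

Duplicate-flagged reads are excluded from pileups by default
(`exclude_duplicates`), recorded in the run manifest.

## Annotation

A minimal transcript-model annotator locates the codon from the exon
structure, strand and CDS phase (number of transcript bases before the
first complete codon), translates with the standard genetic code, and
classifies the effect (synonymous / nonsynonymous / stopgain /
noncoding). Minus-strand substitutions are complemented before codon
substitution, and the substitution is reported on the transcript strand
(C>U, A>I). A transcript-base/reference mismatch raises rather than
silently mis-annotating.

## Splice-state quantification

Reads overlapping the first `boundary_width` (default 2) bases of the
downstream exon are classified:

* **spliced** — the CIGAR contains a reference-skip whose span ends
  exactly at the intron's 3′ end;
* **unspliced** — the alignment covers the intron/exon border
  contiguously with aligned bases, starting before the exon;
* **unclassified** — boundary-overlapping reads that start inside the
  downstream exon, or skips at other junctions.

The historical splice/unsplice separation keyed on the mere presence of
an N in the CIGAR; that coarse rule is available (`--cigar-any-n`) but
misclassifies reads spliced at a different junction, so the
junction-anchored rule is the default. Per-class editing uses the class
pileup at the edit site with the permissive re-genotyping thresholds
(≥ 1 alt read, fraction ≥ 0.001) appropriate for quantifying a known
site. Intron retention is reported two ways: the read-based fraction
n_u/(n_s+n_u) at the boundary (primary; a per-molecule quantity), and
the depth ratio mean(intron depth)/mean(flanking-exon depth) clipped to
[0, 1]. Under the generator's fragment-sampling model both converge to
the planted molecule-level retention ρ.

## Sanger peak-ratio estimation

The editing fraction at the trace position is
amp[edited]/(amp[edited]+amp[primary]); only the two relevant channels
enter, matching how chromatogram mixtures are quantified, and no
baseline correction is applied by default (an optional median-baseline
flag exists). Reverse-orientation traces complement both bases before
channel lookup. The estimator is exactly scale-invariant. ABIF trace
extraction (basecall peak locations + analyzed channels) is provided
via Biopython; amplitude tables as TSV are the primary input.

## Association and survival statistics

* **Log-rank**: the standardized two-group statistic
  Z = Σ(d₁ₜ − dₜ n₁ₜ/nₜ) / sqrt(Σ dₜ (n₁ₜ/nₜ)(1−n₁ₜ/nₜ)(nₜ−dₜ)/(nₜ−1)),
  χ² = Z², p from χ²₁. Implemented in-package because the cutpoint
  search needs Z at every split; cross-checked against lifelines.
* **Maxstat cutpoint**: all distinct covariate values whose split
  proportion lies in [0.10, 0.90] (the conventional bounds) are
  candidate cutpoints; the
  |Z|-maximizing value is returned, ties toward the smaller value. The
  log-rank p reported at the selected cutoff is **not** corrected for
  the selection; the null rejection rate of that naive p exceeds the
  nominal level (a property the test suite asserts). Interpret it as a
  descriptive quantity.
* **Cox HR for a binary group**: Newton maximization of the Breslow
  partial likelihood (closed-form score/information for one binary
  covariate), HR = exp(β) with Wald 95% CI from observed information.
  Breslow tie handling is the simplest defensible choice; with
  continuous times it coincides with Efron and matches lifelines to
  numerical tolerance. All events in one group ⇒ monotone likelihood;
  the HR is flagged non-estimable rather than reported at a boundary.
* **Kaplan–Meier** curves via lifelines (cross-checked against a direct
  product-limit computation in the tests).
* **Expression screen**: per-gene Pearson r of expression against
  editing, per cohort; genes ranked by unweighted mean r across
  cohorts, ties broken by smaller Fisher-combined p; zero-variance
  genes get missing r and fall to the tail. p-values use the t
  transform with n−2 df.
* **DE ranking**: score = logFC · (−log₁₀ p), descending; p = 0 is
  clamped to the smallest positive float and flagged.

No correction is applied across the survival endpoints (TTT, OS); each
endpoint is reported on its own.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the
study conditions.

* **Locus geometry**: 68 bp upstream exon, 7,116 bp intron, 122 bp
  downstream exon, edit site 11 bases into the downstream exon at the
  middle C of a TCG codon (so C>U is an S>L recoding); plus- or
  minus-strand variants (minus plants the genomic G>A equivalent).
* **Templates, not reads**: each RNA read is drawn from a transcript
  molecule that either retains the intron (probability ρ) or not, and
  carries the edit with the class rate (e_u retained, e_s spliced,
  default e_s = 0). This encodes the claim that editing marks
  molecules. Junction-read simulation places every read across both the
  border and the edit site (depth 500 per sample by default);
  depth-uniform simulation allocates fragments proportionally to
  ρ-weighted valid start counts, with templates extended one read
  length beyond the modeled exons (they are interior segments of a
  longer mRNA) — under this standard fragment model both retention
  estimators converge to ρ.
* **Couplings**: ρ = 0.1 + 0.6·e_u + N(0, 0.03²) clipped to [0, 1];
  per-sample e_u is 0 with probability 0.3 (unedited patients) and
  Beta(2, 3) otherwise, giving overall editing percentages in the
  0–40% range typical of the biomarker. The regulator gene's expression
  is 5 + b·z(editing) + N(0, σ²) with b = 2, σ = 1 — an effect size
  stated as a standardized slope, giving population r = b/√(b²+σ²) ≈
  0.89 — among 499 independent N(0, 1) genes.
* **Survival**: exponential with hazard 0.3 for samples at or below the
  editing threshold (the 40th-percentile order statistic) and 0.1 above
  it (editing protective, hazard ratio 3 for low vs high), independent
  uniform censoring on [0, 18] yielding ≈ 30% censoring.
* **Sequencing error**: uniform substitution at ε = 0.001 per base; no
  indel errors (the indel-context filter is exercised with hand-built
  fixtures instead). Base qualities ~ N(37, 3²) clipped to [2, 41].
* **Site panel**: 6 recurrently edited sites (planted in ≥ 2 samples at
  VAF ~ U(0.10, 0.50), RNA coverage ~ U(30, 100), DNA coverage 50),
  2 singleton sites, 20 clean sites, and one recurrent decoy inside an
  HLA-named gene; an independent validation cohort re-edits a fixed
  60% subset of the recurrent sites.
* **Reproducibility**: all randomness flows from
  `numpy.random.SeedSequence(seed)`, with one spawned stream per sample
  and fixed streams for panel/validation/expression/survival, so a
  cohort is byte-identical across runs and extending the cohort leaves
  earlier samples' data unchanged.

**What the synthetic experiments do not show.** Reads are simulated
without soft clips, mapping ambiguity, duplicate structure, GC or
fragment-length bias, and the error model is strand-symmetric and
uniform; pass rates on these data bound what the pipeline can do under
its own assumptions and say nothing about aligner-induced artifacts in
real cohorts. Expression is Gaussian rather than count-distributed, so
the screen's ranking behavior on over-dispersed counts is untested
here.

## Problem sizes and numerical choices

The shipped experiments use 40-sample cohorts at boundary depth 500,
100-seed replicates for the screen (3 cohorts × 40 samples × 500
genes) and survival (n = 100) analyses — sizes at which every recovery
property stabilizes while a full run stays in seconds on one CPU.
Fisher tests use scipy's exact implementation (validated exhaustively
against direct hypergeometric enumeration for all tables with margins
≤ 12); Newton iterations stop at |step| < 1e-10 with steps clipped to
±2 and |β| > 15 treated as divergence; ranking ties are broken
deterministically (alphabetical for alt alleles, smaller value for
cutpoints, stable sorts in rankings).

## Cutpoint localization: a known limitation

The maxstat argmax is far noisier than the test statistic itself. At
hazard ratio 3, n = 100, ~30% censoring, the selected cutoff's offset
from the planted threshold has a sampling sd of several order
statistics (median offset 0, IQR spanning a few ranks); the selected
value is the correct threshold to within a handful of adjacent sample
values, not to one. Single-order-statistic localization is not
achievable at this effect size, and consumers of the cutoff should
treat it as an estimate with that granularity. The hazard ratio and
the maximal statistic, by contrast, are recovered accurately (HR
geometric mean within a few percent of truth over replicates).
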