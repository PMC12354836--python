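# editscan

Discovery and quantification of C-to-U RNA editing from matched DNA/RNA
sequencing, with splice-state-resolved editing at an exon/intron
junction, Sanger peak-ratio estimation, expression–editing correlation
screening, and survival association via maximally selected rank
statistics.

## The problem

C-to-U editing — enzymatic deamination of cytidine, read as C→T in
sequencing of plus-strand transcripts (G→A for minus-strand genes) —
can recode proteins (e.g. an S→L substitution when the middle C of a
UCG serine codon is edited). Detecting it from sequencing requires
separating true RNA/DNA differences from sequencing error, alignment
artifacts and genomic variants, and the biology of interest here is
splice-state specific: editing that is largely confined to transcripts
retaining an intron. Downstream, per-patient editing frequency acts as
a continuous biomarker whose prognostic value is assessed by a
data-driven high/low threshold.

`editscan` implements that entire chain as a tested library with a CLI,
exercised end to end on synthetic cohorts with planted ground truth, so
every stage's recovery properties are measurable.

## Methods at the core

**RNA-unique variant calling.** At each site with matched pileups, a
site gate requires mean base quality ≥ 20 and coverage ≥ 6 in both DNA
and RNA. Read-level filters discount alt support at the first/last base
of a read, support confined to a single strand, and support inside
inserted/deleted alignment segments. A call is emitted when RNA
coverage ≥ 8, RNA variant fraction ≥ 0.05 with ≥ 2 clean supporting
reads, DNA alt fraction ≤ 0.02, and a two-sided Fisher exact test on
the DNA-vs-RNA allele table gives p ≤ 0.05. Cohort-level error control
is recurrence (PASS in ≥ 2 samples, non-synonymous), HLA-gene
exclusion, and re-detection in an independent validation cohort.

**Splice-state quantification.** Reads overlapping the first two bases
of the downstream exon are classified by CIGAR: spliced if a
reference-skip (N) ends exactly at the intron's 3′ end, unspliced if
the alignment crosses the border contiguously. Editing is re-genotyped
per class (reported at ≥ 1 alt read and fraction ≥ 0.001), and intron
retention is estimated both as n_unspliced/(n_spliced+n_unspliced) and
as mean intron depth over mean flanking-exon depth.

**Sanger estimation.** At the edited base-call position, editing
fraction = A_T/(A_T + A_C) from the chromatogram peak amplitudes (the
complementary channels for reverse-orientation traces).

**Association and survival.** Genes are ranked by mean per-cohort
Pearson r between expression and editing frequency. The editing high/low
threshold is the maximally selected rank statistic: over every cutpoint
μ with admissible split proportion in [0.10, 0.90], the standardized
two-group log-rank statistic Z(μ) is computed and the |Z|-maximizing μ
selected; group contrast is summarized by a binary-covariate Cox model
(Newton on the Breslow partial likelihood, HR = exp(β) with Wald CI),
log-rank p and Kaplan–Meier curves. The quoted log-rank p at a
maxstat-selected cutoff is uncorrected for selection and is reported as
such.

**Synthetic cohorts.** The generator plants, per sample: editing rates
per splice class (e_s on spliced, e_u on intron-retained templates),
retention ρ = 0.1 + 0.6·e_u + N(0, 0.03²), a regulator gene with
expression coupled to standardized editing, and exponential survival
whose hazard drops threefold above the 40th-percentile editing
threshold. Editing is applied per template molecule, sequencing error
is uniform at 0.1% per base, and every sample owns a spawned RNG
stream, so cohorts are byte-reproducible and extensible.

## Worked example

```bash
editscan run --out results/e2e --n 40 --seed 0
```

runs simulate → call → recurrence/validation → splice → screen →
survival and prints a summary. On this cohort it reports:

```
"call":    {"n_recurrent": 6, "recurrent_exact": true, "validated_exact": true}
"splice":  {"editing_retention_r": 0.951, "max_vaf_spliced": 0.0028}
"sanger":  {"max_abs_diff": 0.027}
"screen":  {"regulator_rank": 1}
"survive": {"os": {"cutoff": 2.08, "hr_low_vs_high": 9.2, "logrank_p": 4.8e-07}, ...}
```

Reading: all 6 planted recurrent editing sites (and none besides) pass
the filter chain and recurrence, and the validation subset is recovered
exactly; spliced-class editing stays at the error floor while overall
editing depth correlates with intron retention at r = 0.95; the Sanger
peak-ratio estimate agrees with the sequencing VAF within 0.03; the
planted expression regulator ranks first in the correlation screen; and
the survival cutpoint search lands near the planted threshold with
editing-low patients at elevated hazard.

The same stages are available as numbered drivers under `analysis/`
(`01_simulate_cohort.py` … `05_survival.py`), each a thin narrative
script over the library that writes its tables under `results/`, and as
individual subcommands (`editscan call`, `splice`, `sanger`, `screen`,
`survive`) operating on files (text pileups, SAM, TSV).

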