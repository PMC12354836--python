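"""VCF 4.2 output for editing-site calls (plus-strand ref/alt convention)."""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pysam

from editscan.model import EditingSiteCall

# Every read-level or site-level filter the caller can assign.
FILTER_DESCRIPTIONS = {
    "site_quality": "Mean base quality below threshold in DNA or RNA",
    "site_coverage": "Coverage below threshold in DNA or RNA",
    "no_coverage": "No observations at the site",
    "read_end_support": "Alt support only at first/last base of reads",
    "strand_bias": "Alt support restricted to a single strand",
    "indel_context": "Alt support only within inserted/deleted regions",
    "low_rna_cov": "RNA coverage below calling threshold",
    "low_rna_vaf": "RNA variant fraction below calling threshold",
    "low_alt_support": "Fewer alt reads than required for a confident call",
    "dna_shared": "Variant also present in DNA above the allowed fraction",
    "not_significant": "Fisher exact DNA-vs-RNA test not significant",
    "hla_gene": "Variant inside an excluded HLA gene",
}


def write_vcf(calls: Sequence[EditingSiteCall], path: str | Path) -> None:
    """Write calls as VCF 4.2; unsorted input is sorted before writing."""
    header = pysam.VariantHeader()
    for name, desc in FILTER_DESCRIPTIONS.items():
        header.filters.add(name, None, None, desc)
    header.info.add("SAMPLE", 1, "String", "Sample the call was made in")
    header.info.add("DNA_DP", 1, "Integer", "DNA coverage")
    header.info.add("DNA_ALT", 1, "Integer", "DNA alt read count")
    header.info.add("RNA_DP", 1, "Integer", "RNA coverage")
    header.info.add("RNA_ALT", 1, "Integer", "RNA alt read count")
    header.info.add("DNA_VAF", 1, "Float", "DNA variant allele fraction")
    header.info.add("RNA_VAF", 1, "Float", "RNA variant allele fraction")
    header.info.add("FISHER_P", 1, "Float", "Two-sided Fisher exact p, DNA vs RNA")
    header.info.add("GENE", 1, "String", "Gene symbol from annotation")
    header.info.add("EFFECT", 1, "String", "Coding effect")
    header.info.add("AA", 1, "String", "Amino-acid change")
    header.info.add("EDIT_CLASS", 1, "String", "Substitution on the transcript strand")
    for chrom in dict.fromkeys(c.site.chrom for c in calls):
        header.contigs.add(chrom)
    ordered = sorted(calls, key=lambda c: (c.site.chrom, c.site.pos, c.sample_id))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in ordered:
            rec = out.new_record(
                contig=call.site.chrom,
                start=call.site.pos - 1,
                stop=call.site.pos,
                alleles=(call.site.ref_base, call.site.alt_base),
            )
            if call.filters:
                for f in sorted(call.filters):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            rec.info["SAMPLE"] = call.sample_id or "."
            rec.info["DNA_DP"] = call.dna_cov
            rec.info["DNA_ALT"] = call.dna_alt
            rec.info["RNA_DP"] = call.rna_cov
            rec.info["RNA_ALT"] = call.rna_alt
            rec.info["DNA_VAF"] = round(call.dna_vaf, 4)
            rec.info["RNA_VAF"] = round(call.rna_vaf, 4)
            rec.info["FISHER_P"] = call.fisher_p
            if call.annotation is not None:
                rec.info["GENE"] = call.annotation.gene
                rec.info["EFFECT"] = call.annotation.effect
                if call.annotation.effect != "noncoding":
                    rec.info["AA"] = call.annotation.hgvs_p
                rec.info["EDIT_CLASS"] = call.annotation.edit_class_on_transcript.replace(
                    ">", "-"
                )
            out.write(rec)


def read_vcf_calls(path: str | Path) -> list[EditingSiteCall]:
    """Read back calls written by :func:`write_vcf` (round-trip support)."""
    from editscan.model import GenomicSite

    calls: list[EditingSiteCall] = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            filters = set(rec.filter.keys()) - {"PASS"}
            calls.append(
                EditingSiteCall(
                    site=GenomicSite(rec.chrom, rec.pos, rec.ref, rec.alts[0]),
                    sample_id=str(rec.info.get("SAMPLE", ".")),
                    dna_cov=int(rec.info["DNA_DP"]),
                    dna_alt=int(rec.info["DNA_ALT"]),
                    rna_cov=int(rec.info["RNA_DP"]),
                    rna_alt=int(rec.info["RNA_ALT"]),
                    fisher_p=float(rec.info["FISHER_P"]),
                    filters=filters,
                )
            )
    return calls
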