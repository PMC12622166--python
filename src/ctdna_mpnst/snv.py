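"""SNV/indel filtering, background-panel polishing, and severity ranking.

cfDNA calls are retained when allele fraction exceeds 0.0005 (strict) with
alternate-allele depth of at least 8; tumor calls need AF above 0.05 and are
additionally dropped when flagged for contamination, germline origin, or
normal artifact.  A panel of healthy plasma samples polishes recurrent
technical artifacts: any variant seen in more than 10% of panel samples is
removed (with the default 12-sample panel that means removal at >= 2
carriers).  Consequence annotations (Sequence Ontology terms plus
PolyPhen/SIFT predictions) map onto a 0-6 ordinal severity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core import GeneRegistry, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "Severity",
    "VariantCall",
    "FilterDecision",
    "FilterThresholds",
    "filter_cfdna_variant",
    "filter_tumor_variant",
    "background_panel_filter",
    "classify_consequence",
    "gene_severity_summary",
    "read_vcf",
    "write_vcf",
    "write_decisions",
]


class Severity(IntEnum):
    """Ordinal variant-severity scale; higher is more severe."""

    OTHER = 0
    SYNONYMOUS = 1
    NON_DISRUPTING_MISSENSE = 2
    VUS = 3
    SPLICE_ALTERING = 4
    PROTEIN_DISRUPTING_MISSENSE = 5
    LOF = 6


#: truncating loss-of-function consequence terms
_LOF_TERMS = {
    "frameshift_variant",
    "stop_gained",
    "start_lost",
}
_SPLICE_TERMS = {
    "splice_donor_variant": "donor",
    "splice_acceptor_variant": "acceptor",
    "splice_region_variant": "region",
}
_KNOWN_OTHER = {
    "inframe_deletion",
    "inframe_insertion",
    "stop_lost",
    "stop_retained_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
    "non_coding_transcript_exon_variant",
}


@dataclass
class VariantCall:
    """One annotated SNV/indel observation in one sample."""

    interval: GenomicInterval
    ref: str
    alt: str
    sample_id: str
    af: float
    alt_depth: int
    total_depth: int
    callers: frozenset[str] = frozenset()
    consequence: str = ""
    polyphen_damaging: bool | None = None
    sift_deleterious: bool | None = None
    gene: str | None = None
    filter_flags: frozenset[str] = frozenset()
    is_coding: bool = True
    population_af: float | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.key}")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} > total_depth {self.total_depth} at {self.key}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, 0-based pos, ref, alt) identity across samples."""
        return (self.interval.chrom, self.interval.start, self.ref, self.alt)


@dataclass
class FilterDecision:
    """Audit-trail record: a variant is retained iff no reason codes accrued."""

    variant: VariantCall
    reason_codes: list[str] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return not self.reason_codes


@dataclass
class FilterThresholds:
    """Tunable filter thresholds.

    AF comparisons are strict (> not >=) by default, matching the
    retention rule "AF > 0.0005"; set ``strict_af=False`` to include the
    boundary.  ``panel_max_frac`` is the fraction of background-panel
    samples above which a variant is treated as a recurrent artifact.
    """

    cfdna_min_af: float = 0.0005
    tumor_min_af: float = 0.05
    min_alt_depth: int = 8
    strict_af: bool = True
    panel_max_frac: float = 0.10
    population_af_max: float = 0.001
    # high-confidence gate: >=2 callers, or 1 caller with strong read support
    min_callers: int = 2
    single_caller_min_alt: int = 15
    require_high_confidence: bool = False


_TUMOR_FLAG_REASONS = {
    "contamination": "CONTAMINATION",
    "germline": "GERMLINE_MATCH",
    "normal_artifact": "NORMAL_ARTIFACT",
}


def _af_fails(af: float, threshold: float, strict: bool) -> bool:
    return af <= threshold if strict else af < threshold


def _common_reasons(v: VariantCall, t: FilterThresholds) -> list[str]:
    reasons = []
    if v.population_af is not None and v.population_af > t.population_af_max:
        reasons.append("POPULATION_FREQ")
    if t.require_high_confidence:
        if len(v.callers) < t.min_callers and v.alt_depth < t.single_caller_min_alt:
            reasons.append("LOW_CONFIDENCE")
    return reasons


def filter_cfdna_variant(v: VariantCall, thresholds: FilterThresholds | None = None) -> FilterDecision:
    """Apply the plasma retention rule; reasons accumulate, never short-circuit."""
    t = thresholds or FilterThresholds()
    if v.total_depth == 0:
        raise ValueError(f"total_depth is zero for {v.key}")
    reasons = []
    if _af_fails(v.af, t.cfdna_min_af, t.strict_af):
        reasons.append("AF_BELOW_MIN")
    if v.alt_depth < t.min_alt_depth:
        reasons.append("ALT_DEPTH_LOW")
    for flag, code in _TUMOR_FLAG_REASONS.items():
        if flag in v.filter_flags:
            reasons.append(code)
    reasons.extend(_common_reasons(v, t))
    return FilterDecision(variant=v, reason_codes=reasons)


def filter_tumor_variant(v: VariantCall, thresholds: FilterThresholds | None = None) -> FilterDecision:
    """Tumor retention rule: AF > 0.05, alt depth >= 8, no disqualifying flags."""
    t = thresholds or FilterThresholds()
    if v.total_depth == 0:
        raise ValueError(f"total_depth is zero for {v.key}")
    reasons = []
    if _af_fails(v.af, t.tumor_min_af, t.strict_af):
        reasons.append("AF_BELOW_MIN")
    if v.alt_depth < t.min_alt_depth:
        reasons.append("ALT_DEPTH_LOW")
    for flag, code in _TUMOR_FLAG_REASONS.items():
        if flag in v.filter_flags:
            reasons.append(code)
    reasons.extend(_common_reasons(v, t))
    return FilterDecision(variant=v, reason_codes=reasons)


def background_panel_filter(
    variants: Iterable[VariantCall],
    panel_genotypes: Mapping[tuple, int],
    panel_size: int,
    max_frac: float = 0.10,
) -> list[FilterDecision]:
    """Remove variants observed in more than ``max_frac`` of panel samples.

    ``panel_genotypes`` maps (chrom, pos, ref, alt) to the number of panel
    samples carrying the variant.  With a 12-sample panel and the default
    10% rule, removal kicks in at 2 or more carriers.
    """
    if panel_size < 1:
        raise ValueError("background panel is empty; the panel filter cannot run")
    decisions = []
    for v in variants:
        carriers = panel_genotypes.get(v.key, 0)
        reasons = ["BACKGROUND_PANEL"] if carriers / panel_size > max_frac else []
        decisions.append(FilterDecision(variant=v, reason_codes=reasons))
    return decisions


def apply_chip_mask(
    decisions: Iterable[FilterDecision], registry: GeneRegistry
) -> list[FilterDecision]:
    """Append CHIP_GENE reasons for variants in clonal-hematopoiesis genes."""
    chip = set(registry.chip_genes)
    out = []
    for d in decisions:
        if d.variant.gene in chip:
            d.reason_codes.append("CHIP_GENE")
        out.append(d)
    return out


def filter_variants(
    variants: Sequence[VariantCall],
    mode: str,
    thresholds: FilterThresholds | None = None,
    panel_genotypes: Mapping[tuple, int] | None = None,
    panel_size: int | None = None,
    registry: GeneRegistry | None = None,
) -> list[FilterDecision]:
    """Full filter chain: threshold rules, panel polishing, CHIP masking.

    Returns exactly one decision per input variant; retained and rejected
    sets partition the input.
    """
    t = thresholds or FilterThresholds()
    base = filter_cfdna_variant if mode == "cfdna" else filter_tumor_variant
    decisions = [base(v, t) for v in variants]
    if panel_genotypes is not None:
        if not panel_size:
            raise ValueError("panel_size required with panel_genotypes")
        panel = background_panel_filter(variants, panel_genotypes, panel_size, t.panel_max_frac)
        for d, p in zip(decisions, panel):
            d.reason_codes.extend(p.reason_codes)
    if registry is not None:
        apply_chip_mask(decisions, registry)
    return decisions


def classify_consequence(v: VariantCall) -> Severity:
    """Map a Sequence Ontology consequence to the ordinal severity scale.

    Missense splits on the two prediction tools: damaging by both ->
    protein-disrupting; benign by both -> likely-not-disrupting; one tool
    damaging or predictions absent -> VUS.  Unrecognized terms map to
    OTHER with a logged warning rather than crashing.
    """
    terms = {t.strip() for t in v.consequence.replace("&", ",").split(",") if t.strip()}
    if terms & _LOF_TERMS:
        return Severity.LOF
    if terms & set(_SPLICE_TERMS):
        return Severity.SPLICE_ALTERING
    if "missense_variant" in terms:
        if v.polyphen_damaging and v.sift_deleterious:
            return Severity.PROTEIN_DISRUPTING_MISSENSE
        if v.polyphen_damaging is False and v.sift_deleterious is False:
            return Severity.NON_DISRUPTING_MISSENSE
        return Severity.VUS
    if "synonymous_variant" in terms:
        return Severity.SYNONYMOUS
    unknown = terms - _KNOWN_OTHER
    if unknown:
        logger.warning("unrecognized consequence term(s) %s mapped to OTHER", sorted(unknown))
    return Severity.OTHER


def splice_subtype(v: VariantCall) -> str | None:
    """Donor/acceptor/region annotation, recorded but collapsed for features."""
    terms = {t.strip() for t in v.consequence.replace("&", ",").split(",")}
    for term, sub in _SPLICE_TERMS.items():
        if term in terms:
            return sub
    return None


def gene_severity_summary(
    variants: Sequence[VariantCall],
    registry: GeneRegistry,
    genes: Sequence[str] | None = None,
) -> dict[str, dict]:
    """Per-gene highest severity rank and multi-hit flag for one sample.

    Only coding, filter-retained variants should be passed in.  CDKN2A and
    CDKN2B collapse to the merged CDKN2A/B locus.  Genes with no retained
    variant report rank 0 and ``multi_hit=False``.
    """
    from .core import CDKN2AB, SV_FEATURE_GENES

    if genes is None:
        genes = [CDKN2AB, "TP53", "SUZ12", "EED"]
    summary = {g: {"max_rank": 0, "multi_hit": False, "n_variants": 0} for g in genes}
    for v in variants:
        if not v.is_coding:
            continue
        g = registry.snv_gene(v.gene)
        if g not in summary:
            continue
        rank = int(classify_consequence(v))
        entry = summary[g]
        entry["n_variants"] += 1
        entry["max_rank"] = max(entry["max_rank"], rank)
        entry["multi_hit"] = entry["n_variants"] >= 2
    return summary


# --- VCF input/output --------------------------------------------------------

_VCF_INFO_FIELDS = [
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ", ".", "String", "Consequence terms (Sequence Ontology)"),
    ("PP_DMG", "1", "Integer", "PolyPhen damaging (1) or benign (0)"),
    ("SIFT_DEL", "1", "Integer", "SIFT deleterious (1) or tolerated (0)"),
    ("POP_AF", "1", "Float", "Population allele frequency (gnomAD-style)"),
    ("CALLERS", ".", "String", "Supporting variant callers"),
    ("FLAGS", ".", "String", "Upstream filter flags"),
    ("CODING", "1", "Integer", "Coding-region variant (1) or noncoding (0)"),
]

_CONTIG_LENGTHS = {str(i): 250_000_000 for i in range(1, 23)} | {
    "X": 156_000_000,
    "Y": 60_000_000,
    "MT": 16_600,
}


def _build_header(sample_ids: Sequence[str]):
    import pysam

    header = pysam.VariantHeader()
    for contig, length in _CONTIG_LENGTHS.items():
        header.contigs.add(contig, length=length)
    for name, number, vtype, desc in _VCF_INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("AF", "1", "Float", "Allele fraction")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    for s in sample_ids:
        header.add_sample(s)
    return header


def write_vcf(variants: Sequence[VariantCall], path: str | Path, sample_id: str) -> None:
    """Write single-sample annotated calls as an uncompressed VCF."""
    import pysam

    header = _build_header([sample_id])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda x: (x.interval.chrom, x.interval.start)):
            rec = out.new_record(
                contig=v.interval.chrom,
                start=v.interval.start,
                stop=v.interval.start + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["GENE"] = v.gene or "."
            rec.info["CSQ"] = v.consequence or "."
            if v.polyphen_damaging is not None:
                rec.info["PP_DMG"] = int(v.polyphen_damaging)
            if v.sift_deleterious is not None:
                rec.info["SIFT_DEL"] = int(v.sift_deleterious)
            if v.population_af is not None:
                rec.info["POP_AF"] = v.population_af
            if v.callers:
                rec.info["CALLERS"] = ",".join(sorted(v.callers))
            if v.filter_flags:
                rec.info["FLAGS"] = ",".join(sorted(v.filter_flags))
            rec.info["CODING"] = int(v.is_coding)
            sample = rec.samples[sample_id]
            sample["GT"] = (0, 1)
            sample["AF"] = v.af
            sample["AD"] = (v.total_depth - v.alt_depth, v.alt_depth)
            sample["DP"] = v.total_depth
            out.write(rec)


def read_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read annotated calls from a VCF written by this pipeline.

    VCF 1-based positions convert to internal 0-based half-open intervals
    at this boundary.
    """
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        target = sample_id or (samples[0] if samples else None)
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            fmt = rec.samples[target]
            info = rec.info
            gene = info.get("GENE")
            csq = info.get("CSQ")
            if isinstance(csq, tuple):
                csq = ",".join(csq)
            callers = info.get("CALLERS", ())
            flags = info.get("FLAGS", ())
            ad = fmt.get("AD")
            alt_depth = int(ad[1]) if ad and ad[1] is not None else 0
            pp = info.get("PP_DMG")
            sift = info.get("SIFT_DEL")
            calls.append(
                VariantCall(
                    interval=GenomicInterval(chrom, rec.start, rec.start + len(rec.ref)),
                    ref=rec.ref,
                    alt=rec.alts[0],
                    sample_id=target,
                    af=float(fmt.get("AF") or 0.0),
                    alt_depth=alt_depth,
                    total_depth=int(fmt.get("DP") or 0),
                    callers=frozenset(callers if isinstance(callers, tuple) else (callers,))
                    - {None},
                    consequence=csq if csq and csq != "." else "",
                    polyphen_damaging=None if pp is None else bool(pp),
                    sift_deleterious=None if sift is None else bool(sift),
                    gene=None if gene in (None, ".") else gene,
                    filter_flags=frozenset(flags if isinstance(flags, tuple) else (flags,))
                    - {None},
                    is_coding=bool(info.get("CODING", 1)),
                    population_af=info.get("POP_AF"),
                )
            )
    return calls


def panel_genotype_map(panel_calls: Mapping[str, Sequence[VariantCall]]) -> dict[tuple, int]:
    """Collapse per-panel-sample calls into a carrier-count map by variant key."""
    counts: dict[tuple, int] = {}
    for sample_variants in panel_calls.values():
        for key in {v.key for v in sample_variants}:
            counts[key] = counts.get(key, 0) + 1
    return counts


def write_decisions(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    """Write the audit trail: one row per input variant, retained + reasons."""
    import pandas as pd

    rows = [
        {
            "chrom": d.variant.interval.chrom,
            "pos": d.variant.interval.start + 1,  # 1-based for human eyes
            "ref": d.variant.ref,
            "alt": d.variant.alt,
            "sample_id": d.variant.sample_id,
            "af": d.variant.af,
            "alt_depth": d.variant.alt_depth,
            "retained": d.retained,
            "reason_codes": ";".join(d.reason_codes),
        }
        for d in decisions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
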