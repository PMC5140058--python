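"""Multi-caller somatic call-set merging and filtering.

Somatic SNVs are retained when called by at least ``min_callers`` tools and
supported by a variant allele fraction (VAF) of at least ``min_vaf``
(defaults: >=2 tools, VAF >=5%). Indels are retained when called by both of
two tools, after left-normalization, with the same VAF filter. Consensus
read depths and VAF are taken from the first supporting caller in a fixed
priority order (alphabetical unless overridden), since per-caller depths at
the same site generally disagree slightly.

Coordinates are 1-based inclusive (VCF convention); interval masks are
half-open [start, end). Multi-allelic records are split before matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pysam
from pyfaidx import Fasta

from .contexts import normalize_snv
from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SomaticVariant:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    alt_depth: int
    total_depth: int
    callers: frozenset
    variant_class: str  # SNV | insertion | deletion
    substitution: str | None = None  # pyrimidine-strand, SNVs only
    context: str | None = None

    def __post_init__(self):
        if not self.callers:
            raise DomainError(f"variant {self.key} has no supporting caller")
        expected = classify_alleles(self.ref, self.alt)
        if expected != self.variant_class:
            raise DomainError(
                f"variant {self.key}: class {self.variant_class} inconsistent with alleles")

    @property
    def key(self):
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass
class CallSet:
    caller: str
    sample: str
    variants: list = field(default_factory=list)

    def __post_init__(self):
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise FormatError(f"duplicate variant keys in call set {self.caller}")

    def by_key(self) -> dict:
        return {v.key: v for v in self.variants}


def _depths_from_record(rec, alt_index: int):
    """Extract (alt_depth, total_depth) for one alt allele of a VCF record.

    Primary dialect: FORMAT/AD on the first sample. Fallback for
    tier-count dialects (AU/CU/GU/TU as emitted by some SNV callers).
    """
    sample = rec.samples[list(rec.samples)[0]]
    ad = sample.get("AD")
    if ad is not None and ad[0] is not None:
        alt_depth = int(ad[alt_index + 1])
        dp = sample.get("DP")
        total = int(dp) if dp is not None else int(sum(x for x in ad if x is not None))
        return alt_depth, total
    tier = {b: sample.get(f"{b}U") for b in "ACGT"}
    if all(v is not None for v in tier.values()):
        alt_base = rec.alts[alt_index]
        counts = {b: (v[0] if isinstance(v, tuple) else v) for b, v in tier.items()}
        total = int(sum(counts.values()))
        return int(counts[alt_base]), total
    raise FormatError(
        f"no depth fields (AD or tier counts) at {rec.chrom}:{rec.pos} {rec.ref}>{rec.alts}")


def read_caller_vcf(path, caller: str, sample: str | None = None) -> CallSet:
    """Read one caller's VCF into a CallSet.

    Keeps PASS (or unfiltered) records only; splits multi-allelic records
    into bi-allelic variants.
    """
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_label = sample or (list(vcf.header.samples)[0] if vcf.header.samples else "sample")
        for rec in vcf:
            filters = list(rec.filter)
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts):
                alt_depth, total = _depths_from_record(rec, ai)
                variants.append(SomaticVariant(
                    chromosome=rec.chrom,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    alt_depth=alt_depth,
                    total_depth=total,
                    callers=frozenset([caller]),
                    variant_class=classify_alleles(rec.ref, alt),
                ))
    return CallSet(caller, sample_label, variants)


def _check_same_sample(callsets):
    samples = {cs.sample for cs in callsets}
    if len(samples) > 1:
        raise DomainError(f"call sets from different samples: {sorted(samples)}")


def consensus_snvs(
    callsets: list,
    min_callers: int = 2,
    min_vaf: float = 0.05,
    caller_priority: list | None = None,
) -> list:
    """SNVs called by >= ``min_callers`` tools with consensus VAF >= ``min_vaf``.

    Output order is deterministic (genomic coordinate); the ``callers``
    field of each retained variant records every supporting tool.
    """
    if len(callsets) < 2:
        raise DomainError("consensus requires at least two call sets")
    _check_same_sample(callsets)
    priority = caller_priority or sorted(cs.caller for cs in callsets)
    rank = {c: i for i, c in enumerate(priority)}
    support: dict = {}
    for cs in callsets:
        for v in cs.variants:
            if v.variant_class != "SNV":
                continue
            support.setdefault(v.key, []).append((cs.caller, v))
    out = []
    for key in sorted(support):
        entries = sorted(support[key], key=lambda cv: rank.get(cv[0], len(rank)))
        if len(entries) < min_callers:
            continue
        lead = entries[0][1]
        if lead.vaf < min_vaf:
            continue
        out.append(replace(lead, callers=frozenset(c for c, _ in entries)))
    return out


def left_normalize(chromosome, position, ref, alt, reference=None):
    """Left-normalize an indel representation.

    Trims shared trailing then leading bases, then (when a reference is
    supplied) left-shifts the allele pair while the variant representation
    can be extended with the preceding reference base.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    if reference is not None:
        while len(ref) != len(alt) and ref[-1] == alt[-1] and position > 1:
            prev = str(reference[chromosome][position - 2]).upper()
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            position -= 1
    return chromosome, position, ref, alt


def consensus_indels(
    callset_a: CallSet,
    callset_b: CallSet,
    min_vaf: float = 0.05,
    reference=None,
    caller_priority: list | None = None,
) -> list:
    """Indels present in both call sets (after left-normalization) with
    VAF >= ``min_vaf``."""
    _check_same_sample([callset_a, callset_b])
    for cs in (callset_a, callset_b):
        for v in cs.variants:
            if v.variant_class == "SNV":
                raise DomainError(
                    f"SNV {v.key} found in indel call set {cs.caller}")
    priority = caller_priority or sorted([callset_a.caller, callset_b.caller])
    rank = {c: i for i, c in enumerate(priority)}
    norm: dict = {}
    for cs in (callset_a, callset_b):
        for v in cs.variants:
            nk = left_normalize(v.chromosome, v.position, v.ref, v.alt, reference)
            norm.setdefault(nk, []).append((cs.caller, v))
    out = []
    for nk in sorted(norm):
        entries = norm[nk]
        if len({c for c, _ in entries}) < 2:
            continue
        entries.sort(key=lambda cv: rank.get(cv[0], len(rank)))
        lead = entries[0][1]
        if lead.vaf < min_vaf:
            continue
        chrom, pos, ref, alt = nk
        out.append(SomaticVariant(
            chromosome=chrom, position=pos, ref=ref, alt=alt,
            alt_depth=lead.alt_depth, total_depth=lead.total_depth,
            callers=frozenset(c for c, _ in entries),
            variant_class=classify_alleles(ref, alt),
        ))
    return out


def annotate_context(variants: list, reference_fasta) -> list:
    """Attach pyrimidine-normalized trinucleotide contexts to SNVs.

    ``reference_fasta`` is a path or an open ``pyfaidx.Fasta``. Variants at
    contig edges keep ``context=None`` with a logged warning; non-SNVs pass
    through unchanged.
    """
    fasta = reference_fasta if isinstance(reference_fasta, Fasta) else Fasta(str(reference_fasta))
    out = []
    for v in variants:
        if v.variant_class != "SNV":
            out.append(v)
            continue
        contig = fasta[v.chromosome]
        if v.position < 2 or v.position > len(contig) - 1:
            logger.warning("variant %s at contig edge; context unavailable", v.key)
            out.append(v)
            continue
        five = str(contig[v.position - 2]).upper()
        ref_base = str(contig[v.position - 1]).upper()
        three = str(contig[v.position]).upper()
        if ref_base != v.ref.upper():
            raise FormatError(
                f"reference mismatch at {v.chromosome}:{v.position}: "
                f"FASTA has {ref_base}, variant has {v.ref}")
        sub, ctx = normalize_snv(v.ref, v.alt, five, three)
        out.append(replace(v, substitution=sub, context=ctx))
    return out


def mutation_burden(variants: list, coding_mask=None) -> int:
    """Count variants, optionally restricted to half-open mask intervals."""
    if coding_mask is None:
        return len(variants)
    count = 0
    for v in variants:
        for chrom, start, end in coding_mask:
            if v.chromosome == chrom and start <= v.position < end:
                count += 1
                break
    return count


def write_variant_table(variants: list, path, sample: str) -> None:
    """Tab-delimited variant table for downstream stages."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tvaf\talt_depth\tdepth\t"
                 "callers\tclass\tsubstitution\tcontext\n")
        for v in variants:
            fh.write(f"{sample}\t{v.chromosome}\t{v.position}\t{v.ref}\t{v.alt}\t"
                     f"{v.vaf:.6f}\t{v.alt_depth}\t{v.total_depth}\t"
                     f"{','.join(sorted(v.callers))}\t{v.variant_class}\t"
                     f"{v.substitution or '.'}\t{v.context or '.'}\n")


def read_variant_table(path) -> list:
    """Inverse of :func:`write_variant_table`; returns (sample, variants)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns={"class": "vclass"})
    variants = []
    sample = None
    for r in df.itertuples(index=False):
        sample = r.sample
        variants.append(SomaticVariant(
            chromosome=str(r.chrom), position=int(r.pos), ref=r.ref, alt=r.alt,
            alt_depth=int(r.alt_depth), total_depth=int(r.depth),
            callers=frozenset(str(r.callers).split(",")),
            variant_class=r.vclass,
            substitution=None if r.substitution == "." else r.substitution,
            context=None if r.context == "." else r.context,
        ))
    return sample, variants
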