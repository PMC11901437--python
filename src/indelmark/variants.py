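"""InDel variant domain model and VCF I/O.

Variants use standard VCF semantics: 1-based positions and anchored alleles
(REF and ALT share a leading base for insertions/deletions). The length of an
InDel is the net difference ``|len(REF) - len(ALT)|`` after the shared anchor,
its type is an insertion when the ALT is longer, a deletion otherwise.

Call sets are held per sample per reference frame in a :class:`VariantTable`
keyed by ``(chromosome, position, ref_allele, alt_allele)`` so that the same
event called in different samples matches exactly once both calls have been
left-normalized against the same reference (:func:`left_normalize`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

import pysam

__all__ = [
    "IndelType",
    "Zygosity",
    "InDelVariant",
    "VariantTable",
    "TypeSummary",
    "LengthHistogram",
    "VcfParseError",
    "ReferenceMismatchError",
    "parse_vcf",
    "vcf_samples",
    "left_normalize",
    "normalize_table",
    "summarize_types",
    "length_histogram",
    "write_vcf",
]

_DNA_RE = re.compile(r"^[ACGTN]+$")

VariantKey = tuple[str, int, str, str]


class IndelType(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    MISSING = "missing"


class VcfParseError(ValueError):
    """Raised when a VCF stream cannot be parsed into InDel records."""


class ReferenceMismatchError(ValueError):
    """Raised when a variant's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True, slots=True)
class InDelVariant:
    """One normalized insertion/deletion call in a fixed reference frame.

    ``reference_id`` identifies the genome the coordinates refer to
    (``"maternal"`` for the apple assembly, ``"paternal"`` for the pear
    assembly in the motivating cross).
    """

    reference_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity = Zygosity.HETEROZYGOUS

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if not allele or not _DNA_RE.match(allele):
                raise ValueError(f"{name}_allele must be non-empty uppercase DNA, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")
        if len(self.ref_allele) == len(self.alt_allele):
            raise ValueError("not an InDel: REF and ALT have equal length")

    @property
    def indel_type(self) -> IndelType:
        if len(self.alt_allele) > len(self.ref_allele):
            return IndelType.INSERTION
        return IndelType.DELETION

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def key(self) -> VariantKey:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    def with_zygosity(self, zygosity: Zygosity) -> "InDelVariant":
        return replace(self, zygosity=zygosity)


class VariantTable:
    """All InDel calls for one sample against one reference genome.

    Entries with missing genotype (``./.``) are retained with
    ``Zygosity.MISSING`` — a missing call is indistinguishable from low
    coverage — but are excluded from :meth:`informative_keys`, which defines
    presence for all downstream set arithmetic.
    """

    def __init__(
        self,
        sample_id: str,
        reference_id: str,
        variants: Iterable[InDelVariant] = (),
    ) -> None:
        self.sample_id = sample_id
        self.reference_id = reference_id
        self._variants: dict[VariantKey, InDelVariant] = {}
        for v in variants:
            self.add(v)

    def add(self, variant: InDelVariant) -> None:
        if variant.reference_id != self.reference_id:
            raise ValueError(
                f"variant frame {variant.reference_id!r} != table frame {self.reference_id!r}"
            )
        if variant.key in self._variants:
            raise ValueError(f"duplicate variant key {variant.key}")
        self._variants[variant.key] = variant

    def __len__(self) -> int:
        return len(self._variants)

    def __iter__(self) -> Iterator[InDelVariant]:
        return iter(self._variants.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._variants

    def get(self, key: VariantKey) -> InDelVariant | None:
        return self._variants.get(key)

    def keys(self) -> set[VariantKey]:
        return set(self._variants)

    def informative_keys(self) -> set[VariantKey]:
        """Keys with an observed genotype (heterozygous or homozygous)."""
        return {k for k, v in self._variants.items() if v.zygosity is not Zygosity.MISSING}

    def missing_keys(self) -> set[VariantKey]:
        return {k for k, v in self._variants.items() if v.zygosity is Zygosity.MISSING}

    def contains_informative(self, key: VariantKey) -> bool:
        v = self._variants.get(key)
        return v is not None and v.zygosity is not Zygosity.MISSING

    def sorted_variants(self) -> list[InDelVariant]:
        return [self._variants[k] for k in sorted(self._variants)]


# ---------------------------------------------------------------------------
# VCF parsing


def vcf_samples(path: str) -> list[str]:
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def _zygosity_for_alt(gt: tuple, alt_index: int) -> Zygosity | None:
    """Map a GT tuple to the zygosity of ALT allele ``alt_index`` (1-based).

    Returns ``None`` when the sample does not carry this allele (e.g. 0/0 or
    a different ALT at a multi-allelic site): such records are dropped from
    the sample's table.
    """
    if gt is None or all(a is None for a in gt):
        return Zygosity.MISSING
    n = sum(1 for a in gt if a == alt_index)
    if n == 0:
        return None
    if n == 1:
        return Zygosity.HETEROZYGOUS
    return Zygosity.HOMOZYGOUS


def parse_vcf(path: str, sample_id: str, reference_id: str) -> VariantTable:
    """Read the InDel calls of one sample from a VCF v4.x file.

    Only records where REF and ALT lengths differ are retained (SNPs and MNPs
    are excluded); multi-allelic records are decomposed into one entry per ALT
    allele. Genotypes map as 0/1 -> heterozygous, 1/1 -> homozygous,
    ./. -> missing; 0/0 (allele not carried) drops the record.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        if sample_id not in samples:
            raise VcfParseError(
                f"sample {sample_id!r} not in VCF; available samples: {samples}"
            )
        table = VariantTable(sample_id=sample_id, reference_id=reference_id)
        n_records = 0
        last_locus = "start of file"
        try:
            for rec in vcf:
                n_records += 1
                last_locus = f"{rec.chrom}:{rec.pos}"
                if not rec.alts:
                    continue
                gt = rec.samples[sample_id].get("GT")
                for i, alt in enumerate(rec.alts, start=1):
                    if alt is None or alt.startswith("<") or not _DNA_RE.match(alt.upper()):
                        continue  # symbolic / breakend alleles
                    ref = rec.ref.upper()
                    alt = alt.upper()
                    if len(ref) == len(alt):
                        continue  # SNP / MNP
                    zyg = _zygosity_for_alt(gt, i)
                    if zyg is None:
                        continue
                    variant = InDelVariant(
                        reference_id=reference_id,
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        zygosity=zyg,
                    )
                    if variant.key in table:
                        continue  # duplicated record, keep first
                    table.add(variant)
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"malformed VCF record #{n_records + 1} (after {last_locus}) in {path}: {exc}"
            ) from exc
    return table


def write_vcf(
    table: VariantTable,
    path: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Emit a single-sample VCF v4.2 with a GT field for the table's sample."""
    gt_for = {
        Zygosity.HETEROZYGOUS: "0/1",
        Zygosity.HOMOZYGOUS: "1/1",
        Zygosity.MISSING: "./.",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = contig_lengths or {}
        chroms = sorted({v.chromosome for v in table} | set(contigs))
        for chrom in chroms:
            if chrom in contigs:
                fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{table.sample_id}\n"
        )
        for v in table.sorted_variants():
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gt_for[v.zygosity]}\n"
            )


# ---------------------------------------------------------------------------
# Left normalization


def _ref_base(seq, pos: int) -> str:
    """1-based single base from a string or pyfaidx record."""
    return str(seq[pos - 1 : pos]).upper()


def _ref_slice(seq, pos: int, length: int) -> str:
    return str(seq[pos - 1 : pos - 1 + length]).upper()


def left_normalize(variant: InDelVariant, reference: Mapping[str, object]) -> InDelVariant:
    """Left-align an InDel against its reference sequence.

    Standard left-alignment: shared trailing bases are trimmed (extending the
    alleles leftward with the preceding reference base whenever one allele
    would become empty), then shared leading bases beyond the single anchor
    are trimmed. Idempotent; preserves the InDel's type and length.
    """
    seq = reference[variant.chromosome]
    pos = variant.position
    ref = variant.ref_allele
    alt = variant.alt_allele
    if _ref_slice(seq, pos, len(ref)) != ref:
        raise ReferenceMismatchError(
            f"REF {ref!r} at {variant.chromosome}:{pos} disagrees with reference "
            f"{_ref_slice(seq, pos, len(ref))!r}"
        )
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos <= 1:
                # fully shifted to the contig start: anchor on the right
                # with the next reference base (bcftools convention)
                nxt = _ref_base(seq, pos + len(ref))
                if not nxt:
                    raise ValueError(
                        f"variant spans all of {variant.chromosome}; cannot anchor"
                    )
                ref, alt = ref + nxt, alt + nxt
                break
            prev = _ref_base(seq, pos - 1)
            ref, alt = prev + ref, prev + alt
            pos -= 1
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(variant, position=pos, ref_allele=ref, alt_allele=alt)


def normalize_table(table: VariantTable, reference: Mapping[str, object]) -> VariantTable:
    """Left-normalize every variant; keys colliding after normalization merge."""
    out = VariantTable(sample_id=table.sample_id, reference_id=table.reference_id)
    for v in table:
        nv = left_normalize(v, reference)
        if nv.key not in out:
            out.add(nv)
    return out


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True, slots=True)
class TypeSummary:
    """Insertion/deletion and zygosity partition of a call set.

    Both partitions must conserve the total:
    ``n_insertion + n_deletion == n_total`` and
    ``n_heterozygous + n_homozygous + n_missing == n_total``.
    """

    n_total: int
    n_insertion: int
    n_deletion: int
    n_heterozygous: int
    n_homozygous: int
    n_missing: int = 0
    region_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = (
            self.n_total,
            self.n_insertion,
            self.n_deletion,
            self.n_heterozygous,
            self.n_homozygous,
            self.n_missing,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_insertion + self.n_deletion != self.n_total:
            raise ValueError("insertion/deletion partition does not sum to n_total")
        if self.n_heterozygous + self.n_homozygous + self.n_missing != self.n_total:
            raise ValueError("zygosity partition does not sum to n_total")

    @classmethod
    def from_parts(
        cls,
        n_insertion: int,
        n_deletion: int,
        n_heterozygous: int,
        n_homozygous: int,
        n_missing: int = 0,
        region_counts: Mapping[str, int] | None = None,
    ) -> "TypeSummary":
        """Build a summary from partition counts, deriving the total."""
        return cls(
            n_total=n_insertion + n_deletion,
            n_insertion=n_insertion,
            n_deletion=n_deletion,
            n_heterozygous=n_heterozygous,
            n_homozygous=n_homozygous,
            n_missing=n_missing,
            region_counts=dict(region_counts or {}),
        )


def summarize_types(table: VariantTable, region_labels: Mapping[VariantKey, str] | None = None) -> TypeSummary:
    """Count insertion/deletion and zygosity classes of a table.

    ``region_labels`` (key -> region label) optionally fills the per-region
    tally of the summary.
    """
    n_ins = n_del = n_het = n_hom = n_mis = 0
    regions: dict[str, int] = {}
    for v in table:
        if v.indel_type is IndelType.INSERTION:
            n_ins += 1
        else:
            n_del += 1
        if v.zygosity is Zygosity.HETEROZYGOUS:
            n_het += 1
        elif v.zygosity is Zygosity.HOMOZYGOUS:
            n_hom += 1
        else:
            n_mis += 1
        if region_labels is not None:
            label = region_labels.get(v.key, "unannotated")
            regions[label] = regions.get(label, 0) + 1
    return TypeSummary.from_parts(n_ins, n_del, n_het, n_hom, n_mis, regions)


@dataclass(frozen=True)
class LengthHistogram:
    """InDel length counts binned at ascending bp thresholds.

    Bin ``i`` holds lengths in ``(breaks[i-1], breaks[i]]``; an extra final
    bin holds lengths strictly greater than the last break, so with a break
    at 50 bp the "greater than 50 bp" class is the last bin.
    """

    breaks: tuple[int, ...]
    counts: tuple[int, ...]

    @property
    def n_total(self) -> int:
        return sum(self.counts)

    @property
    def labels(self) -> tuple[str, ...]:
        labs = []
        lo = 0
        for b in self.breaks:
            labs.append(f"{lo + 1}-{b}" if b > lo + 1 else f"{b}")
            lo = b
        labs.append(f">{self.breaks[-1]}")
        return tuple(labs)

    def count_greater_than(self, threshold: int) -> int:
        """Count of lengths strictly greater than ``threshold`` (must be a break)."""
        if threshold not in self.breaks:
            raise ValueError(f"threshold {threshold} is not a histogram break")
        i = self.breaks.index(threshold)
        return sum(self.counts[i + 1 :])


def length_histogram(table: VariantTable, breaks: Iterable[int] = (1, 5, 10, 20, 50)) -> LengthHistogram:
    breaks = tuple(breaks)
    if list(breaks) != sorted(breaks) or len(set(breaks)) != len(breaks):
        raise ValueError("breaks must be strictly ascending")
    counts = [0] * (len(breaks) + 1)
    for v in table:
        length = v.indel_length
        for i, b in enumerate(breaks):
            if length <= b:
                counts[i] += 1
                break
        else:
            counts[-1] += 1
    return LengthHistogram(breaks=breaks, counts=tuple(counts))
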