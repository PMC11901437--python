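"""Gene-region annotation of InDel positions.

Each variant position receives exactly one label from
:data:`REGION_LABELS`, resolved by specificity:

    splicing > 5'/3' UTR > exon > intron > upstream > downstream > intergenic

"splicing" means within :data:`SPLICE_WINDOW` bp of an internal exon-intron
boundary; upstream/downstream are strand-aware windows of ``flank`` bp
(default 1 kb) beyond the gene body. A variant is annotated by the position
of its anchor base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
from intervaltree import IntervalTree

from .variants import InDelVariant, VariantKey, VariantTable

__all__ = [
    "REGION_LABELS",
    "SPLICE_WINDOW",
    "Gene",
    "GeneModelSet",
    "AnnotationError",
    "annotate_region",
    "annotate_table",
]

SPLICE_WINDOW = 2

# Most specific first; annotate_region returns the first label that applies.
REGION_LABELS = (
    "splicing",
    "five_prime_UTR",
    "three_prime_UTR",
    "exon",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

_PRECEDENCE = {label: i for i, label in enumerate(REGION_LABELS)}


class AnnotationError(KeyError):
    """Raised when a variant cannot be annotated (unknown chromosome)."""


@dataclass(frozen=True)
class Gene:
    """One gene model: 1-based closed intervals, exons sorted by start."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad gene interval [{self.start}, {self.end}]")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s}, {e}] outside gene body of {self.gene_id}")

    def internal_boundaries(self) -> tuple[int, ...]:
        """Exon edges that border an intron (gene ends excluded)."""
        bounds = []
        for s, e in self.exons:
            if s > self.start:
                bounds.append(s)
            if e < self.end:
                bounds.append(e)
        return tuple(bounds)


class GeneModelSet:
    """Per-chromosome gene models with fast positional lookup."""

    def __init__(self, genes: Iterable[Gene], chromosome_lengths: Mapping[str, int] | None = None):
        self.genes = tuple(genes)
        self.chromosome_lengths = dict(chromosome_lengths or {})
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            if gene.chromosome in self.chromosome_lengths:
                if gene.end > self.chromosome_lengths[gene.chromosome]:
                    raise ValueError(
                        f"gene {gene.gene_id} exceeds {gene.chromosome} length"
                    )
            tree = self._trees.setdefault(gene.chromosome, IntervalTree())
            tree.addi(gene.start, gene.end + 1, gene)
        for chrom in self.chromosome_lengths:
            self._trees.setdefault(chrom, IntervalTree())

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    @classmethod
    def from_gff3(cls, path: str, chromosome_lengths: Mapping[str, int] | None = None) -> "GeneModelSet":
        """Load gene, exon and UTR features from a GFF3 file."""
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes = []
        for g in db.features_of_type("gene"):
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(g, featuretype="exon"))
            )
            utr5 = tuple(
                sorted((f.start, f.end) for f in db.children(g, featuretype="five_prime_UTR"))
            )
            utr3 = tuple(
                sorted((f.start, f.end) for f in db.children(g, featuretype="three_prime_UTR"))
            )
            genes.append(
                Gene(
                    gene_id=g.id,
                    chromosome=g.seqid,
                    start=g.start,
                    end=g.end,
                    strand=g.strand if g.strand in "+-" else "+",
                    exons=exons or ((g.start, g.end),),
                    utr5=utr5,
                    utr3=utr3,
                )
            )
        return cls(genes, chromosome_lengths)

    def _labels_for_gene(self, gene: Gene, pos: int, flank: int) -> list[str]:
        labels = []
        if gene.start <= pos <= gene.end:
            if any(abs(pos - b) <= SPLICE_WINDOW for b in gene.internal_boundaries()):
                labels.append("splicing")
            if any(s <= pos <= e for s, e in gene.utr5):
                labels.append("five_prime_UTR")
            if any(s <= pos <= e for s, e in gene.utr3):
                labels.append("three_prime_UTR")
            if any(s <= pos <= e for s, e in gene.exons):
                labels.append("exon")
            else:
                labels.append("intron")
        else:
            before = gene.start - flank <= pos < gene.start
            after = gene.end < pos <= gene.end + flank
            if gene.strand == "+":
                if before:
                    labels.append("upstream")
                if after:
                    labels.append("downstream")
            else:
                if before:
                    labels.append("downstream")
                if after:
                    labels.append("upstream")
        return labels

    def annotate(self, chromosome: str, position: int, flank: int = 1000) -> str:
        if chromosome not in self._trees:
            raise AnnotationError(
                f"chromosome {chromosome!r} absent from gene models "
                f"(known: {sorted(self._trees)})"
            )
        candidates: list[str] = []
        for iv in self._trees[chromosome].overlap(position - flank, position + flank + 1):
            candidates.extend(self._labels_for_gene(iv.data, position, flank))
        if not candidates:
            return "intergenic"
        return min(candidates, key=_PRECEDENCE.__getitem__)

    def write_gff3(self, path: str) -> None:
        """Emit the models as GFF3 (gene/mRNA/exon/UTR features)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(self.chromosome_lengths):
                fh.write(f"##sequence-region {chrom} 1 {self.chromosome_lengths[chrom]}\n")
            for gene in sorted(self.genes, key=lambda g: (g.chromosome, g.start)):
                gid = gene.gene_id
                base = f"{gene.chromosome}\tindelmark\t"
                tail = f"\t.\t{gene.strand}\t.\t"
                fh.write(f"{base}gene\t{gene.start}\t{gene.end}{tail}ID={gid}\n")
                mid = f"{gid}.t1"
                fh.write(f"{base}mRNA\t{gene.start}\t{gene.end}{tail}ID={mid};Parent={gid}\n")
                for i, (s, e) in enumerate(gene.exons, 1):
                    fh.write(f"{base}exon\t{s}\t{e}{tail}ID={mid}.exon{i};Parent={mid}\n")
                for i, (s, e) in enumerate(gene.utr5, 1):
                    fh.write(
                        f"{base}five_prime_UTR\t{s}\t{e}{tail}ID={mid}.utr5.{i};Parent={mid}\n"
                    )
                for i, (s, e) in enumerate(gene.utr3, 1):
                    fh.write(
                        f"{base}three_prime_UTR\t{s}\t{e}{tail}ID={mid}.utr3.{i};Parent={mid}\n"
                    )


def annotate_region(variant: InDelVariant, models: GeneModelSet, flank: int = 1000) -> str:
    """Label one variant by the gene region of its anchor position."""
    return models.annotate(variant.chromosome, variant.position, flank)


def annotate_table(
    table: VariantTable, models: GeneModelSet, flank: int = 1000
) -> dict[VariantKey, str]:
    return {v.key: annotate_region(v, models, flank) for v in table}
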