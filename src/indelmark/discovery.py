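"""Parent-specific InDel detection and the marker-development funnel.

The funnel proceeds: parental call sets (one reference frame) -> set
difference on exact variant keys -> parent-specific InDels -> offspring
coverage (fraction of all supplied progeny sharing the same call) -> length
and coverage filters (both strict) -> candidate markers with chromosome-
indexed identifiers and a flanked target region for primer design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .variants import InDelVariant, VariantTable

__all__ = [
    "ParentSpecificInDel",
    "CandidateMarker",
    "FunnelReport",
    "FrameMismatchError",
    "call_parent_specific",
    "offspring_coverage",
    "select_candidates",
    "chromosome_distribution",
    "candidate_frame",
]


class FrameMismatchError(ValueError):
    """Raised when call sets from different reference frames are compared."""


@dataclass(frozen=True, slots=True)
class ParentSpecificInDel:
    """An InDel present in exactly one parent's call set.

    ``other_parent_missing`` flags sites where the other parent had a missing
    genotype (treated as absence, but low coverage cannot be excluded from the
    VCF alone).
    """

    variant: InDelVariant
    specific_to: str  # "maternal" | "paternal"
    other_parent_missing: bool = False
    n_offspring_informative: int | None = None
    n_offspring_total: int | None = None

    def __post_init__(self) -> None:
        if self.specific_to not in ("maternal", "paternal"):
            raise ValueError(f"specific_to must be maternal|paternal, got {self.specific_to!r}")

    @property
    def offspring_coverage(self) -> float | None:
        if self.n_offspring_total in (None, 0):
            return None
        return self.n_offspring_informative / self.n_offspring_total


@dataclass(frozen=True, slots=True)
class CandidateMarker:
    """A parent-specific InDel retained as a PCR marker candidate.

    ``target_region`` is the flanked interval around the InDel that the
    primers must bracket; ``expected_allele_sizes`` is the
    (allele-with-InDel, allele-without) amplicon-length pair, filled once
    primers are designed.
    """

    marker_id: str
    source: ParentSpecificInDel
    target_region: tuple[str, int, int]
    expected_allele_sizes: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        chrom, start, end = self.target_region
        v = self.source.variant
        if not (start <= v.position <= end):
            raise ValueError("target_region does not contain the variant")
        if self.expected_allele_sizes is not None:
            with_indel, without = self.expected_allele_sizes
            if abs(with_indel - without) != v.indel_length:
                raise ValueError("allele size difference must equal indel length")

    @property
    def variant(self) -> InDelVariant:
        return self.source.variant

    def with_allele_sizes(self, with_indel: int, without: int) -> "CandidateMarker":
        return replace(self, expected_allele_sizes=(with_indel, without))


@dataclass(frozen=True)
class FunnelReport:
    """Stage counts of the marker-development funnel for one parental side."""

    specific_to: str
    n_parental: int
    n_specific: int
    n_length_pass: int
    n_candidates: int

    def as_dict(self) -> dict[str, int | str]:
        return {
            "specific_to": self.specific_to,
            "n_parental": self.n_parental,
            "n_specific": self.n_specific,
            "n_length_pass": self.n_length_pass,
            "n_candidates": self.n_candidates,
        }


def call_parent_specific(
    maternal_table: VariantTable, paternal_table: VariantTable
) -> tuple[list[ParentSpecificInDel], list[ParentSpecificInDel]]:
    """Split parental calls into maternal- and paternal-specific sets.

    A variant is maternal-specific iff its key is informatively present in
    the maternal table and not informatively present in the paternal table
    (and symmetrically). Variants present in both are discarded. Both tables
    must be in the same reference frame and left-normalized.
    """
    if maternal_table.reference_id != paternal_table.reference_id:
        raise FrameMismatchError(
            f"reference frames differ: {maternal_table.reference_id!r} vs "
            f"{paternal_table.reference_id!r}"
        )
    m_present = maternal_table.informative_keys()
    p_present = paternal_table.informative_keys()
    m_missing = maternal_table.missing_keys()
    p_missing = paternal_table.missing_keys()

    maternal_specific = [
        ParentSpecificInDel(
            variant=maternal_table.get(k),
            specific_to="maternal",
            other_parent_missing=k in p_missing,
        )
        for k in sorted(m_present - p_present)
    ]
    paternal_specific = [
        ParentSpecificInDel(
            variant=paternal_table.get(k),
            specific_to="paternal",
            other_parent_missing=k in m_missing,
        )
        for k in sorted(p_present - m_present)
    ]
    return maternal_specific, paternal_specific


def offspring_coverage(
    specific: Iterable[ParentSpecificInDel],
    progeny_tables: Sequence[VariantTable],
) -> list[ParentSpecificInDel]:
    """Fill the offspring coverage of each parent-specific InDel.

    Coverage counts progeny whose table informatively contains the same
    variant key; the denominator is all supplied progeny, matching the
    "fraction of the offspring individuals" definition rather than a
    callable-only denominator.
    """
    if not progeny_tables:
        raise ValueError("coverage is undefined for an empty progeny list")
    specific = list(specific)
    if specific:
        frame = specific[0].variant.reference_id
        for t in progeny_tables:
            if t.reference_id != frame:
                raise FrameMismatchError(
                    f"progeny table {t.sample_id!r} frame {t.reference_id!r} != {frame!r}"
                )
    n_total = len(progeny_tables)
    out = []
    for s in specific:
        n_inf = sum(1 for t in progeny_tables if t.contains_informative(s.variant.key))
        out.append(replace(s, n_offspring_informative=n_inf, n_offspring_total=n_total))
    return out


def _chromosome_rank(chromosome: str) -> tuple[int, str]:
    digits = re.sub(r"\D", "", chromosome)
    return (int(digits) if digits else 10**9, chromosome)


def chromosome_label(chromosome: str) -> str:
    digits = re.sub(r"\D", "", chromosome)
    return str(int(digits)) if digits else chromosome


def select_candidates(
    specific_with_coverage: Iterable[ParentSpecificInDel],
    min_length: int = 50,
    min_coverage: float = 0.5,
    flank: int = 200,
) -> list[CandidateMarker]:
    """Apply the strict length and coverage filters and assign marker IDs.

    A marker is retained iff ``indel_length > min_length`` (strictly greater,
    so a 50 bp InDel at the default threshold is excluded) and
    ``offspring_coverage > min_coverage``. IDs follow the
    ``InDel{chromosome}-{rank}`` convention with ranks assigned by position
    within each chromosome; ordering is deterministic.
    """
    kept = []
    for s in specific_with_coverage:
        cov = s.offspring_coverage
        if cov is None:
            raise ValueError(f"coverage not filled for {s.variant.key}")
        if s.variant.indel_length > min_length and cov > min_coverage:
            kept.append(s)
    kept.sort(key=lambda s: (_chromosome_rank(s.variant.chromosome), s.variant.position))
    markers = []
    rank_in_chrom: dict[str, int] = {}
    for s in kept:
        v = s.variant
        rank = rank_in_chrom.get(v.chromosome, 0) + 1
        rank_in_chrom[v.chromosome] = rank
        marker_id = f"InDel{chromosome_label(v.chromosome)}-{rank}"
        start = max(1, v.position - flank)
        end = v.position + len(v.ref_allele) - 1 + flank
        markers.append(
            CandidateMarker(marker_id=marker_id, source=s, target_region=(v.chromosome, start, end))
        )
    return markers


def chromosome_distribution(
    markers: Iterable[CandidateMarker],
    all_chromosomes: Iterable[str] | None = None,
) -> pd.Series:
    """Per-chromosome marker counts (sums to the number of markers)."""
    counts: dict[str, int] = {c: 0 for c in (all_chromosomes or ())}
    for m in markers:
        chrom = m.target_region[0]
        counts[chrom] = counts.get(chrom, 0) + 1
    ordered = sorted(counts, key=_chromosome_rank)
    return pd.Series([counts[c] for c in ordered], index=ordered, name="n_markers")


def candidate_frame(markers: Iterable[CandidateMarker]) -> pd.DataFrame:
    """Candidate markers as a tidy table (one row per marker)."""
    rows = []
    for m in markers:
        v = m.variant
        rows.append(
            {
                "marker_id": m.marker_id,
                "chromosome": v.chromosome,
                "position": v.position,
                "indel_type": v.indel_type.value,
                "indel_length": v.indel_length,
                "specific_to": m.source.specific_to,
                "offspring_coverage": m.source.offspring_coverage,
                "target_start": m.target_region[1],
                "target_end": m.target_region[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "chromosome",
            "position",
            "indel_type",
            "indel_length",
            "specific_to",
            "offspring_coverage",
            "target_start",
            "target_end",
        ],
    )
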