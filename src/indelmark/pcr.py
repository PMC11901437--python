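"""In-silico PCR: amplicon prediction, gel-band resolution, hybrid calling.

A marker is scored per individual from the band sizes its primer pair would
amplify off the individual's two haplotypes. The authentication rule is the
codominant two-band rule: an individual showing both the maternal and the
paternal band size at one or more markers is a true hybrid; a single maternal
band leaves it unidentified.

Amplicon sizes use the 5'-start to 5'-start inclusive convention on the plus
strand; the only size property downstream logic relies on — the difference
between the two allelic amplicons equals the InDel length — is convention
independent. Primer matching is an exact string match: thermodynamics,
mismatch tolerance and PCR failure modes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PrimerPair",
    "BandPattern",
    "GenotypeCall",
    "HybridCall",
    "AmbiguousPrimerError",
    "MarkerInvalidError",
    "MAX_PRODUCT_BP",
    "GEL_RESOLUTION_BP",
    "revcomp",
    "design_primers",
    "predict_amplicons",
    "resolve_bands",
    "genotype_individual",
    "call_hybrid",
]

MAX_PRODUCT_BP = 3000
GEL_RESOLUTION_BP = 20  # conservative for a 2.0% agarose gel
MIN_PRIMER_LEN = 15

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AmbiguousPrimerError(ValueError):
    """A primer has more than one exact binding site on a haplotype."""


class MarkerInvalidError(ValueError):
    """Parental band patterns are non-polymorphic at the chosen resolution."""


@dataclass(frozen=True, slots=True)
class PrimerPair:
    marker_id: str
    forward_seq: str
    reverse_seq: str
    annealing_temperature: float = 60.0  # metadata only

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if len(seq) < MIN_PRIMER_LEN:
                raise ValueError(f"{name} primer shorter than {MIN_PRIMER_LEN} bp")


@dataclass(frozen=True, slots=True)
class BandPattern:
    marker_id: str
    individual_id: str
    bands: frozenset[int]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.bands):
            raise ValueError("band sizes must be positive")
        if len(self.bands) > 2:
            raise ValueError("a diploid individual shows at most two distinct bands")


class GenotypeCall(str, Enum):
    BOTH_PARENTS = "both_parents"
    MATERNAL_ONLY = "maternal_only"
    PATERNAL_ONLY = "paternal_only"
    AMBIGUOUS = "ambiguous"
    MISSING = "missing"


@dataclass(frozen=True, slots=True)
class HybridCall:
    """Outcome of the two-band rule over all markers of one individual."""

    individual_id: str
    is_true_hybrid: bool
    supporting_markers: tuple[str, ...]
    determined: bool = True

    def __post_init__(self) -> None:
        if self.is_true_hybrid != bool(self.supporting_markers):
            raise ValueError("is_true_hybrid must hold iff supporting markers exist")


def design_primers(marker, reference: Mapping[str, object], primer_length: int = 20) -> PrimerPair:
    """Exact-match primers at the two ends of a marker's target region.

    The forward primer is the plus-strand sequence at the region start, the
    reverse primer the reverse complement of the region's last bases, so the
    reference amplicon spans exactly the target region.
    """
    chrom, start, end = marker.target_region
    seq = str(reference[chrom][start - 1 : end]).upper()
    if len(seq) < 2 * primer_length:
        raise ValueError(f"target region of {marker.marker_id} too short for primers")
    return PrimerPair(
        marker_id=marker.marker_id,
        forward_seq=seq[:primer_length],
        reverse_seq=revcomp(seq[-primer_length:]),
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    sites = []
    i = haystack.find(needle)
    while i != -1:
        sites.append(i)
        i = haystack.find(needle, i + 1)
    return sites


def predict_amplicons(
    primers: PrimerPair,
    haplotypes: Sequence[str],
    individual_id: str = "",
    max_product: int = MAX_PRODUCT_BP,
) -> BandPattern:
    """Predict the band set a primer pair amplifies off one or two haplotypes.

    Each haplotype contributes at most one band; a haplotype with no forward
    or no reverse site (or an oversized product) simply contributes nothing,
    while more than one exact site for either primer raises
    :class:`AmbiguousPrimerError`. Identical sizes merge.
    """
    if not 1 <= len(haplotypes) <= 2:
        raise ValueError("expected one or two haplotype sequences")
    bands: set[int] = set()
    rev_site_seq = revcomp(primers.reverse_seq)
    for hap in haplotypes:
        hap = hap.upper()
        f_sites = _find_all(hap, primers.forward_seq)
        r_sites = _find_all(hap, rev_site_seq)
        if len(f_sites) > 1 or len(r_sites) > 1:
            raise AmbiguousPrimerError(
                f"multiple binding sites for marker {primers.marker_id}"
            )
        if not f_sites or not r_sites:
            continue
        f0, r0 = f_sites[0], r_sites[0]
        size = r0 + len(primers.reverse_seq) - f0
        if size <= 0 or size > max_product:
            continue
        bands.add(size)
    return BandPattern(
        marker_id=primers.marker_id, individual_id=individual_id, bands=frozenset(bands)
    )


def resolve_bands(pattern: BandPattern, resolution: int = GEL_RESOLUTION_BP) -> BandPattern:
    """Merge gel-indistinguishable bands (closer than ``resolution`` bp).

    Single-linkage over the sorted sizes; each run of bands with adjacent
    gaps below the resolution collapses to its largest member, so the result
    does not depend on input order.
    """
    sizes = sorted(pattern.bands)
    if not sizes:
        return pattern
    merged = []
    run_max = sizes[0]
    prev = sizes[0]
    for s in sizes[1:]:
        if s - prev < resolution:
            run_max = s
        else:
            merged.append(run_max)
            run_max = s
        prev = s
    merged.append(run_max)
    return BandPattern(
        marker_id=pattern.marker_id,
        individual_id=pattern.individual_id,
        bands=frozenset(merged),
    )


def genotype_individual(
    pattern: BandPattern,
    maternal_pattern: BandPattern,
    paternal_pattern: BandPattern,
    resolution: int = GEL_RESOLUTION_BP,
) -> GenotypeCall:
    """Score one individual at one marker against the parental band sizes.

    Requires each parent to show a single band and the two parental bands to
    be gel-distinguishable; a marker violating this is non-polymorphic and
    must be excluded upstream (:class:`MarkerInvalidError`). Band matching is
    exact on resolved sizes.
    """
    if len(maternal_pattern.bands) != 1 or len(paternal_pattern.bands) != 1:
        raise MarkerInvalidError(
            f"marker {pattern.marker_id}: parental patterns must each show one band"
        )
    (m_size,) = maternal_pattern.bands
    (p_size,) = paternal_pattern.bands
    if abs(m_size - p_size) < resolution:
        raise MarkerInvalidError(
            f"marker {pattern.marker_id}: parental bands {m_size}/{p_size} "
            f"indistinguishable at {resolution} bp"
        )
    if not pattern.bands:
        return GenotypeCall.MISSING
    has_m = m_size in pattern.bands
    has_p = p_size in pattern.bands
    if has_m and has_p:
        return GenotypeCall.BOTH_PARENTS
    if has_m:
        return GenotypeCall.MATERNAL_ONLY
    if has_p:
        return GenotypeCall.PATERNAL_ONLY
    return GenotypeCall.AMBIGUOUS


def call_hybrid(calls: Mapping[str, GenotypeCall], individual_id: str) -> HybridCall:
    """Apply the two-band rule: hybrid iff >= 1 marker shows both parents.

    With zero valid (non-missing) marker calls the individual's status is
    undetermined, reported distinctly from "not identified as hybrid".
    """
    valid = {m: c for m, c in calls.items() if c is not GenotypeCall.MISSING}
    if not valid:
        return HybridCall(
            individual_id=individual_id,
            is_true_hybrid=False,
            supporting_markers=(),
            determined=False,
        )
    supporting = tuple(
        sorted(m for m, c in valid.items() if c is GenotypeCall.BOTH_PARENTS)
    )
    return HybridCall(
        individual_id=individual_id,
        is_true_hybrid=bool(supporting),
        supporting_markers=supporting,
    )


def primer_table(primers: Iterable[PrimerPair]) -> "list[dict]":
    return [
        {
            "marker_id": p.marker_id,
            "forward_seq": p.forward_seq,
            "reverse_seq": p.reverse_seq,
            "annealing_temperature": p.annealing_temperature,
        }
        for p in primers
    ]
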