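"""End-to-end orchestration: discovery, genotyping, panels, transferability.

Every stage reads and writes plain-text files (TSV/BED/JSON/VCF/FASTA) so
stages are independently runnable and every report cell is recomputable from
emitted intermediates. Thresholds actually applied are logged to stderr.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import discovery as disc
from .annotate import GeneModelSet
from .discovery import CandidateMarker, FunnelReport, candidate_frame, chromosome_distribution
from .panel import GenotypingMatrix, MarkerPanel, greedy_panel, identification_stats, transferability
from .pcr import (
    GEL_RESOLUTION_BP,
    BandPattern,
    GenotypeCall,
    HybridCall,
    MarkerInvalidError,
    PrimerPair,
    call_hybrid,
    genotype_individual,
    predict_amplicons,
    resolve_bands,
)
from .variants import InDelVariant, VariantTable, normalize_table, parse_vcf, vcf_samples

__all__ = [
    "PipelineConfig",
    "ConfigurationError",
    "DiscoveryResult",
    "IdentifyResult",
    "load_reference",
    "discover",
    "run_discovery",
    "find_linked_paternal",
    "apply_allele",
    "genotype_population",
    "hybrid_calls_from_matrix",
    "identify",
    "run_identify",
]

log = logging.getLogger("indelmark")


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths, thresholds and options driving the pipeline stages."""

    reference_fasta: str = ""
    maternal_vcf: str = ""
    paternal_vcf: str = ""
    progeny_vcf: str = ""
    gff3: str = ""
    outdir: str = "results"
    seed: int = 0
    maternal_sample: str | None = None
    paternal_sample: str | None = None
    min_length: int = 50
    min_coverage: float = 0.5
    gel_resolution: int = GEL_RESOLUTION_BP
    flank: int = 200
    panel_target_rate: float = 1.0
    marker_side: str = "maternal"

    def __post_init__(self) -> None:
        if not 0 <= self.min_coverage <= 1:
            raise ConfigurationError("min_coverage must be in [0, 1]")
        if not 0 <= self.panel_target_rate <= 1:
            raise ConfigurationError("panel_target_rate must be in [0, 1]")
        if self.min_length < 0 or self.gel_resolution < 0 or self.flank < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.marker_side not in ("maternal", "paternal"):
            raise ConfigurationError("marker_side must be maternal|paternal")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def require_inputs(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if not path:
                raise ConfigurationError(f"required input {name!r} not configured")
            if not os.path.exists(path):
                raise ConfigurationError(f"required input {name}={path!r} does not exist")


def load_reference(path: str) -> dict[str, str]:
    """Read a FASTA into chromosome -> sequence strings."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Discovery


@dataclass
class DiscoveryResult:
    funnels: dict[str, FunnelReport]
    maternal_specific: list
    paternal_specific: list
    markers: list[CandidateMarker]
    region_labels: dict = field(default_factory=dict)


def discover(
    maternal_table: VariantTable,
    paternal_table: VariantTable,
    progeny_tables: Sequence[VariantTable],
    min_length: int = 50,
    min_coverage: float = 0.5,
    flank: int = 200,
    marker_side: str = "maternal",
    gene_models: GeneModelSet | None = None,
) -> DiscoveryResult:
    """Run the marker-development funnel on in-memory call sets."""
    if not progeny_tables:
        raise ConfigurationError(
            "marker discovery requires at least one progeny call set "
            "(offspring coverage is undefined otherwise)"
        )
    log.info(
        "discovery filters: indel_length > %d bp, offspring coverage > %.2f "
        "(both strict), flank %d bp, marker side %s",
        min_length,
        min_coverage,
        flank,
        marker_side,
    )
    m_spec, p_spec = disc.call_parent_specific(maternal_table, paternal_table)
    m_cov = disc.offspring_coverage(m_spec, progeny_tables)
    p_cov = disc.offspring_coverage(p_spec, progeny_tables)
    funnels = {}
    for side, table, cov in (
        ("maternal", maternal_table, m_cov),
        ("paternal", paternal_table, p_cov),
    ):
        n_len = sum(1 for s in cov if s.variant.indel_length > min_length)
        n_cand = sum(
            1
            for s in cov
            if s.variant.indel_length > min_length and s.offspring_coverage > min_coverage
        )
        funnels[side] = FunnelReport(
            specific_to=side,
            n_parental=len(table.informative_keys()),
            n_specific=len(cov),
            n_length_pass=n_len,
            n_candidates=n_cand,
        )
    side_cov = m_cov if marker_side == "maternal" else p_cov
    markers = disc.select_candidates(side_cov, min_length, min_coverage, flank)
    region_labels = {}
    if gene_models is not None:
        for m in markers:
            region_labels[m.marker_id] = gene_models.annotate(
                m.variant.chromosome, m.variant.position
            )
    return DiscoveryResult(
        funnels=funnels,
        maternal_specific=m_cov,
        paternal_specific=p_cov,
        markers=markers,
        region_labels=region_labels,
    )


def _parse_inputs(config: PipelineConfig):
    config.require_inputs("reference_fasta", "maternal_vcf", "paternal_vcf", "progeny_vcf")
    reference = load_reference(config.reference_fasta)
    m_sample = config.maternal_sample or vcf_samples(config.maternal_vcf)[0]
    p_sample = config.paternal_sample or vcf_samples(config.paternal_vcf)[0]
    maternal = normalize_table(parse_vcf(config.maternal_vcf, m_sample, "maternal"), reference)
    paternal = normalize_table(parse_vcf(config.paternal_vcf, p_sample, "maternal"), reference)
    progeny = [
        normalize_table(parse_vcf(config.progeny_vcf, s, "maternal"), reference)
        for s in vcf_samples(config.progeny_vcf)
    ]
    return reference, maternal, paternal, progeny


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False, **kw) -> None:
    df.to_csv(path, sep="\t", index=index, **kw)


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """File-based discovery stage: parse, filter, and emit funnel reports."""
    reference, maternal, paternal, progeny = _parse_inputs(config)
    gene_models = None
    if config.gff3:
        config.require_inputs("gff3")
        gene_models = GeneModelSet.from_gff3(config.gff3)
    result = discover(
        maternal,
        paternal,
        progeny,
        config.min_length,
        config.min_coverage,
        config.flank,
        config.marker_side,
        gene_models,
    )
    os.makedirs(config.outdir, exist_ok=True)
    funnel_df = pd.DataFrame([f.as_dict() for f in result.funnels.values()])
    _write_tsv(funnel_df, os.path.join(config.outdir, "funnel.tsv"))
    cand = candidate_frame(result.markers)
    if result.region_labels:
        cand["region"] = cand["marker_id"].map(result.region_labels)
    _write_tsv(cand, os.path.join(config.outdir, "candidates.tsv"))
    with open(os.path.join(config.outdir, "candidates.bed"), "w") as fh:
        for m in result.markers:
            chrom, start, end = m.target_region
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{m.marker_id}\n")
    dist = chromosome_distribution(result.markers, all_chromosomes=sorted(reference))
    _write_tsv(dist.rename_axis("chromosome").reset_index(), os.path.join(config.outdir, "chromosome_distribution.tsv"))
    return result


# ---------------------------------------------------------------------------
# Genotyping


def apply_allele(region_seq: str, region_start: int, variant: InDelVariant) -> str:
    """Apply one variant's ALT allele to a reference region (1-based start)."""
    off = variant.position - region_start
    if off < 0 or off + len(variant.ref_allele) > len(region_seq):
        raise ValueError(f"variant {variant.key} outside region")
    if region_seq[off : off + len(variant.ref_allele)] != variant.ref_allele:
        raise ValueError(f"region disagrees with REF at {variant.key}")
    return region_seq[:off] + variant.alt_allele + region_seq[off + len(variant.ref_allele) :]


def find_linked_paternal(
    marker: CandidateMarker,
    paternal_table: VariantTable,
    maternal_table: VariantTable,
) -> InDelVariant | None:
    """The paternal diagnostic allele amplified by this marker's primers.

    Chosen as the paternal-specific informative call (absent from the
    maternal call set — an allele the mother also carries cannot separate
    hybrids from maternal-only offspring) nearest to the marker position and
    fully contained in the target region (ties: smallest key). Interspecific
    divergence means a marker locus typically carries such an allele; without
    one the paternal band equals the reference-allele band and the marker is
    non-polymorphic.
    """
    chrom, start, end = marker.target_region
    pos = marker.variant.position
    best: InDelVariant | None = None
    for v in paternal_table:
        if v.chromosome != chrom or not (
            start <= v.position and v.position + len(v.ref_allele) - 1 <= end
        ):
            continue
        if not paternal_table.contains_informative(v.key):
            continue
        if maternal_table.contains_informative(v.key):
            continue  # shared allele: not diagnostic of paternal origin
        if best is None or (abs(v.position - pos), v.key) < (abs(best.position - pos), best.key):
            best = v
    return best


def _haplotype_bands(
    primers: PrimerPair,
    region: str,
    region_start: int,
    alleles: Sequence[InDelVariant | None],
    individual_id: str,
    resolution: int,
) -> BandPattern:
    haps = [
        apply_allele(region, region_start, a) if a is not None else region for a in alleles
    ]
    return resolve_bands(predict_amplicons(primers, haps, individual_id), resolution)


def genotype_population(
    reference: Mapping[str, str],
    markers: Sequence[CandidateMarker],
    maternal_table: VariantTable,
    paternal_table: VariantTable,
    progeny_tables: Sequence[VariantTable],
    population_id: str = "discovery",
    resolution: int = GEL_RESOLUTION_BP,
    primers: Mapping[str, PrimerPair] | None = None,
) -> tuple[GenotypingMatrix, dict[str, PrimerPair]]:
    """In-silico PCR of every marker on every progeny individual.

    Per-individual haplotypes carry the marker allele (maternal origin) and
    the linked paternal allele when the individual's call set informatively
    contains them; variation elsewhere in the amplicon is assumed absent, the
    usual in-silico PCR simplification. Markers whose parental patterns are
    not polymorphic at the gel resolution are flagged non-polymorphic and
    their cells set to ``missing``.
    """
    log.info("genotyping %d markers x %d individuals at %d bp gel resolution",
             len(markers), len(progeny_tables), resolution)
    calls: dict[str, dict[str, GenotypeCall]] = {}
    polymorphic: dict[str, bool] = {}
    primer_map: dict[str, PrimerPair] = {}
    for marker in markers:
        chrom, start, end = marker.target_region
        region = str(reference[chrom][start - 1 : end]).upper()
        pp = (primers or {}).get(marker.marker_id) or design_primers_from_region(
            marker, region
        )
        primer_map[marker.marker_id] = pp
        m_allele = (
            marker.variant
            if maternal_table.contains_informative(marker.variant.key)
            else None
        )
        linked = find_linked_paternal(marker, paternal_table, maternal_table)
        m_pattern = _haplotype_bands(pp, region, start, [m_allele], "maternal", resolution)
        p_pattern = _haplotype_bands(pp, region, start, [linked], "paternal", resolution)
        row: dict[str, GenotypeCall] = {}
        try:
            for t in progeny_tables:
                alleles = [
                    marker.variant if t.contains_informative(marker.variant.key) else None,
                    linked if linked is not None and t.contains_informative(linked.key) else None,
                ]
                pattern = _haplotype_bands(pp, region, start, alleles, t.sample_id, resolution)
                row[t.sample_id] = genotype_individual(pattern, m_pattern, p_pattern, resolution)
            polymorphic[marker.marker_id] = True
        except MarkerInvalidError:
            row = {t.sample_id: GenotypeCall.MISSING for t in progeny_tables}
            polymorphic[marker.marker_id] = False
        calls[marker.marker_id] = row
    matrix = GenotypingMatrix.from_calls(population_id, calls, polymorphic)
    return matrix, primer_map


def design_primers_from_region(marker: CandidateMarker, region: str, primer_length: int = 20) -> PrimerPair:
    from .pcr import revcomp

    if len(region) < 2 * primer_length:
        raise ValueError(f"target region of {marker.marker_id} too short for primers")
    return PrimerPair(
        marker_id=marker.marker_id,
        forward_seq=region[:primer_length],
        reverse_seq=revcomp(region[-primer_length:]),
    )


def attach_allele_sizes(
    markers: Sequence[CandidateMarker], reference: Mapping[str, str]
) -> list[CandidateMarker]:
    """Fill expected amplicon sizes (allele with InDel, allele without)."""
    out = []
    for m in markers:
        chrom, start, end = m.target_region
        without = end - start + 1
        v = m.variant
        delta = len(v.alt_allele) - len(v.ref_allele)
        out.append(m.with_allele_sizes(without + delta, without))
    return out


def hybrid_calls_from_matrix(matrix: GenotypingMatrix) -> list[HybridCall]:
    out = []
    for ind in matrix.individuals:
        col = matrix.calls[ind]
        out.append(call_hybrid({m: GenotypeCall(col[m]) for m in matrix.markers}, ind))
    return out


# ---------------------------------------------------------------------------
# Identification reports


@dataclass
class IdentifyResult:
    matrix: GenotypingMatrix
    stats: pd.DataFrame
    hybrid_calls: list[HybridCall]
    panel: MarkerPanel


def identify(matrix: GenotypingMatrix, target_rate: float = 1.0) -> IdentifyResult:
    """Per-marker stats, two-band hybrid calls and the greedy minimal panel."""
    stats = identification_stats(matrix)
    calls = hybrid_calls_from_matrix(matrix)
    panel = greedy_panel(matrix, target_rate=target_rate)
    return IdentifyResult(matrix=matrix, stats=stats, hybrid_calls=calls, panel=panel)


def write_identify_reports(result: IdentifyResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.matrix.to_tsv(os.path.join(outdir, "genotyping_matrix.tsv"))
    _write_tsv(result.stats.reset_index(), os.path.join(outdir, "per_marker_stats.tsv"))
    hc = pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "is_true_hybrid": c.is_true_hybrid,
                "determined": c.determined,
                "supporting_markers": ",".join(c.supporting_markers),
            }
            for c in result.hybrid_calls
        ]
    )
    _write_tsv(hc, os.path.join(outdir, "hybrid_calls.tsv"))
    with open(os.path.join(outdir, "panel.json"), "w") as fh:
        json.dump(result.panel.as_dict(), fh, indent=1, sort_keys=True)


def run_identify(config: PipelineConfig) -> IdentifyResult:
    """File-based identification stage: genotype, score, select the panel."""
    reference, maternal, paternal, progeny = _parse_inputs(config)
    disc_result = discover(
        maternal,
        paternal,
        progeny,
        config.min_length,
        config.min_coverage,
        config.flank,
        config.marker_side,
    )
    matrix, primer_map = genotype_population(
        reference,
        disc_result.markers,
        maternal,
        paternal,
        progeny,
        resolution=config.gel_resolution,
    )
    result = identify(matrix, config.panel_target_rate)
    os.makedirs(config.outdir, exist_ok=True)
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "marker_id": p.marker_id,
                    "forward_seq": p.forward_seq,
                    "reverse_seq": p.reverse_seq,
                    "annealing_temperature": p.annealing_temperature,
                }
                for p in primer_map.values()
            ]
        ),
        os.path.join(config.outdir, "primers.tsv"),
    )
    write_identify_reports(result, config.outdir)
    return result


def transferability_table(
    matrices: Sequence[GenotypingMatrix], reference_marker_list: Sequence[str]
) -> pd.DataFrame:
    """Cross-population transferability summary (one row per population)."""
    rows = [transferability(m, reference_marker_list).as_dict() for m in matrices]
    return pd.DataFrame(rows)
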