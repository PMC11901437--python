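"""Seeded trio-variant simulator with complete truth logs.

Generates, at desk scale, the statistical structure the marker pipeline
assumes: a maternal reference genome; maternal and paternal InDel call sets
in that frame with a controlled parent-specific fraction; gene models placed
so that every annotation label is exercised; Mendelian progeny containing a
configurable fraction of true hybrids (the remainder are maternal-only
individuals, covering both pollen failure and selfing-like origins); and
per-(site, individual) genotyping dropout emitted as missing genotypes.

Two modelling choices matter downstream:

* Parent-specific InDels are planted heterozygous by default, so each is
  transmitted to ~50% of progeny — the segregation behind the observed
  ~50-56% per-marker identification rates. Homozygous planting is available
  as a scenario switch (``specific_zygosity="homozygous"``).
* Every long (marker-eligible, >50 bp) maternal-specific InDel carries a
  linked homozygous paternal divergence allele (a +30 bp insertion at the
  same site, its own VCF record). The two species' haplotypes differ at any
  locus; representing that divergence is what makes the marker codominant:
  the paternal gel band is distinct from both maternal alleles, so a
  maternal-only individual can never display both parental band sizes.
* Maternal-only progeny are a doubled single maternal gamete (homozygous at
  every carried site).

Region-label truth is assigned by construction — positions are placed into
feature windows chosen before annotation runs — so annotation tests compare
against placement truth rather than re-deriving labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import Gene, GeneModelSet
from .variants import (
    InDelVariant,
    VariantKey,
    VariantTable,
    Zygosity,
    left_normalize,
)

__all__ = [
    "SimulationConfig",
    "SimulationConfigError",
    "VariantTruth",
    "TruthLog",
    "ParentSimulation",
    "ProgenySimulation",
    "ValidationSimulation",
    "StudySimulation",
    "simulate_parents",
    "simulate_progeny",
    "simulate_validation_population",
    "simulate_study",
    "write_fasta",
    "write_population_vcf",
]

LINKED_DIVERGENCE_BP = 30  # paternal allele planted at each long maternal marker

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Placement weights over region labels, loosely following the observed
# predominance of intergenic InDels.
REGION_WEIGHTS = {
    "intergenic": 0.55,
    "upstream": 0.12,
    "downstream": 0.12,
    "intron": 0.10,
    "exon": 0.06,
    "five_prime_UTR": 0.02,
    "three_prime_UTR": 0.02,
    "splicing": 0.01,
}

_GENE_SPAN = 3000
_GENE_SPACING = 9000
_GENE_OFFSET = 3000


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters; defaults are the desk-scale study conditions."""

    seed: int = 0
    n_chromosomes: int = 17
    chromosome_length_bp: int = 200_000
    n_parental_indels: int = 2000
    fraction_parent_specific: float = 0.2
    # InDel length mixture: long (marker-eligible) with probability p_long
    p_long: float = 0.3
    short_length_range: tuple[int, int] = (1, 10)
    long_length_range: tuple[int, int] = (51, 120)
    n_progeny: int = 62
    hybrid_fraction: float = 1.0
    transmission_probability: float = 0.5
    dropout_rate: float = 0.1
    specific_zygosity: str = "heterozygous"  # or "homozygous" (transmission 1.0)
    shared_het_fraction: float = 0.65
    # validation (transferability) populations
    validation_sizes: tuple[int, ...] = (46, 76, 40)
    hybrid_fraction_validation: float = 0.85
    marker_loss_fraction: float = 0.2
    reference_id: str = "maternal"

    def __post_init__(self) -> None:
        fractions = {
            "fraction_parent_specific": self.fraction_parent_specific,
            "p_long": self.p_long,
            "hybrid_fraction": self.hybrid_fraction,
            "transmission_probability": self.transmission_probability,
            "dropout_rate": self.dropout_rate,
            "shared_het_fraction": self.shared_het_fraction,
            "hybrid_fraction_validation": self.hybrid_fraction_validation,
            "marker_loss_fraction": self.marker_loss_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {value}")
        for name, value in (
            ("n_chromosomes", self.n_chromosomes),
            ("chromosome_length_bp", self.chromosome_length_bp),
            ("n_parental_indels", self.n_parental_indels),
            ("n_progeny", self.n_progeny),
        ):
            if value < 1:
                raise SimulationConfigError(f"{name} must be positive, got {value}")
        if self.specific_zygosity not in ("heterozygous", "homozygous"):
            raise SimulationConfigError(
                f"specific_zygosity must be heterozygous|homozygous, got {self.specific_zygosity!r}"
            )

    @property
    def n_maternal_specific(self) -> int:
        return round(self.n_parental_indels * self.fraction_parent_specific)

    @property
    def n_paternal_specific(self) -> int:
        return self.n_maternal_specific

    @property
    def n_shared(self) -> int:
        return self.n_parental_indels - self.n_maternal_specific

    def chromosome_names(self) -> list[str]:
        return [f"chr{i:02d}" for i in range(1, self.n_chromosomes + 1)]


@dataclass(frozen=True)
class VariantTruth:
    origin: str  # maternal_specific | paternal_specific | paternal_linked | shared
    indel_length: int
    region_label: str
    linked_to: VariantKey | None = None


@dataclass
class TruthLog:
    """Complete provenance of every emitted record, individual and dropout."""

    variants: dict[VariantKey, VariantTruth] = field(default_factory=dict)
    individual_class: dict[str, str] = field(default_factory=dict)
    dropouts: set = field(default_factory=set)  # {(VariantKey, individual_id)}
    linked_paternal: dict[VariantKey, VariantKey] = field(default_factory=dict)

    def keys_with_origin(self, *origins: str) -> set[VariantKey]:
        return {k for k, t in self.variants.items() if t.origin in origins}

    @property
    def maternal_specific_keys(self) -> set[VariantKey]:
        return self.keys_with_origin("maternal_specific")

    @property
    def paternal_specific_keys(self) -> set[VariantKey]:
        return self.keys_with_origin("paternal_specific", "paternal_linked")

    def hybrids(self) -> list[str]:
        return sorted(i for i, c in self.individual_class.items() if c == "true_hybrid")

    def to_json(self, path: str) -> None:
        def key_str(k: VariantKey) -> str:
            return f"{k[0]}:{k[1]}:{k[2]}:{k[3]}"

        payload = {
            "variants": {
                key_str(k): {
                    "origin": t.origin,
                    "indel_length": t.indel_length,
                    "region_label": t.region_label,
                    "linked_to": key_str(t.linked_to) if t.linked_to else None,
                }
                for k, t in self.variants.items()
            },
            "individual_class": self.individual_class,
            "dropouts": sorted([key_str(k), ind] for k, ind in self.dropouts),
            "linked_paternal": {key_str(k): key_str(v) for k, v in self.linked_paternal.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Placement slots


def _gene_layout(config: SimulationConfig) -> list[Gene]:
    genes = []
    usable = config.chromosome_length_bp - 2 * _GENE_OFFSET
    n_genes = max(0, usable // _GENE_SPACING)
    if n_genes == 0:
        raise SimulationConfigError(
            f"chromosome_length_bp={config.chromosome_length_bp} too short for gene models"
        )
    for ci, chrom in enumerate(config.chromosome_names()):
        for g in range(int(n_genes)):
            s = _GENE_OFFSET + g * _GENE_SPACING
            e = s + _GENE_SPAN - 1
            strand = "+" if (ci + g) % 2 == 0 else "-"
            exons = ((s, s + 599), (s + 1200, s + 1799), (s + 2400, e))
            if strand == "+":
                utr5, utr3 = ((s, s + 149),), ((s + 2850, e),)
            else:
                utr5, utr3 = ((s + 2850, e),), ((s, s + 149),)
            genes.append(
                Gene(
                    gene_id=f"{chrom}.g{g + 1}",
                    chromosome=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    return genes


def _slot_pools(config: SimulationConfig, genes: Sequence[Gene], rng: np.random.Generator):
    """Candidate anchor positions per region label, shuffled once."""
    pools: dict[str, list[tuple[str, int]]] = {label: [] for label in REGION_WEIGHTS}
    tail_margin = 500
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in config.chromosome_names():
        chrom_genes = sorted(by_chrom.get(chrom, ()), key=lambda g: g.start)
        for gene in chrom_genes:
            s = gene.start
            # windows relative to the fixed gene template (see _gene_layout)
            utr_left = [(chrom, p) for p in range(s + 20, s + 131, 55)]
            utr_right = [(chrom, p) for p in range(s + 2860, s + 2971, 55)]
            if gene.strand == "+":
                pools["five_prime_UTR"] += utr_left
                pools["three_prime_UTR"] += utr_right
            else:
                pools["five_prime_UTR"] += utr_right
                pools["three_prime_UTR"] += utr_left
            pools["exon"] += [(chrom, p) for p in range(s + 200, s + 501, 60)]
            pools["intron"] += [(chrom, p) for p in range(s + 650, s + 1151, 60)]
            pools["splicing"].append((chrom, s + 599))
            up = [(chrom, p) for p in range(s - 900, s - 199, 100)]
            down = [(chrom, p) for p in range(gene.end + 200, gene.end + 901, 100)]
            if gene.strand == "+":
                pools["upstream"] += up
                pools["downstream"] += down
            else:
                pools["upstream"] += down
                pools["downstream"] += up
            # intergenic zone in the gap after this gene (>1 kb from any gene)
            gap_start = gene.end + 1200
            gap_end = s + _GENE_SPACING - 1200
            pools["intergenic"] += [(chrom, p) for p in range(gap_start, gap_end + 1, 200)]
        if chrom_genes:
            # after the last per-gene gap, up to the end of the chromosome
            tail_start = chrom_genes[-1].start + _GENE_SPACING
            tail_end = config.chromosome_length_bp - tail_margin
            pools["intergenic"] += [(chrom, p) for p in range(tail_start, tail_end + 1, 200)]
    for label in pools:
        rng.shuffle(pools[label])
    return pools


# ---------------------------------------------------------------------------
# Parent simulation


@dataclass
class ParentSimulation:
    config: SimulationConfig
    reference: dict[str, str]
    maternal_table: VariantTable
    paternal_table: VariantTable
    gene_models: GeneModelSet
    truth: TruthLog

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}

    def write(self, outdir: str) -> None:
        import os

        from .variants import write_vcf

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.reference, os.path.join(outdir, "maternal.fa"))
        write_vcf(self.maternal_table, os.path.join(outdir, "maternal.vcf"), self.contig_lengths())
        write_vcf(self.paternal_table, os.path.join(outdir, "paternal.vcf"), self.contig_lengths())
        self.gene_models.write_gff3(os.path.join(outdir, "genes.gff3"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


def _random_sequences(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    out = {}
    for chrom in config.chromosome_names():
        idx = rng.integers(0, 4, size=config.chromosome_length_bp)
        out[chrom] = _BASES[idx].tobytes().decode("ascii")
    return out


def _draw_length(config: SimulationConfig, rng: np.random.Generator, long: bool | None = None) -> int:
    if long is None:
        long = rng.random() < config.p_long
    lo, hi = config.long_length_range if long else config.short_length_range
    return int(rng.integers(lo, hi + 1))


def _random_insert(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return _BASES[idx].tobytes().decode("ascii")


def _make_variant(
    reference: dict[str, str],
    chrom: str,
    pos: int,
    length: int,
    is_insertion: bool,
    reference_id: str,
    rng: np.random.Generator,
) -> InDelVariant:
    seq = reference[chrom]
    anchor = seq[pos - 1]
    if is_insertion:
        v = InDelVariant(
            reference_id=reference_id,
            chromosome=chrom,
            position=pos,
            ref_allele=anchor,
            alt_allele=anchor + _random_insert(rng, length),
        )
    else:
        if pos + length > len(seq):
            raise SimulationConfigError(f"deletion at {chrom}:{pos} exceeds chromosome")
        v = InDelVariant(
            reference_id=reference_id,
            chromosome=chrom,
            position=pos,
            ref_allele=seq[pos - 1 : pos + length],
            alt_allele=anchor,
        )
    return left_normalize(v, reference)


def _draw_zygosity(config: SimulationConfig, rng: np.random.Generator, specific: bool) -> Zygosity:
    if specific:
        return (
            Zygosity.HETEROZYGOUS
            if config.specific_zygosity == "heterozygous"
            else Zygosity.HOMOZYGOUS
        )
    return (
        Zygosity.HETEROZYGOUS
        if rng.random() < config.shared_het_fraction
        else Zygosity.HOMOZYGOUS
    )


def simulate_parents(config: SimulationConfig) -> ParentSimulation:
    """Plant parental call sets, gene models and truth in the maternal frame."""
    rng = np.random.default_rng([config.seed, 0])
    reference = _random_sequences(config, rng)
    genes = _gene_layout(config)
    models = GeneModelSet(genes, {c: len(s) for c, s in reference.items()})
    pools = _slot_pools(config, genes, rng)

    labels = list(REGION_WEIGHTS)
    weights = np.array([REGION_WEIGHTS[l] for l in labels])
    weights = weights / weights.sum()

    def pop_slot(label: str) -> tuple[str, int]:
        if pools[label]:
            return pools[label].pop()
        if pools["intergenic"]:
            return pools["intergenic"].pop()
        raise SimulationConfigError(
            "chromosomes too short for the requested variant density"
        )

    truth = TruthLog()
    maternal = VariantTable("maternal_parent", config.reference_id)
    paternal = VariantTable("paternal_parent", config.reference_id)

    plan = (
        [("maternal_specific", True)] * config.n_maternal_specific
        + [("paternal_specific", True)] * config.n_paternal_specific
        + [("shared", False)] * config.n_shared
    )
    for origin, specific in plan:
        for _ in range(50):  # retry on (rare) key collision after normalization
            label = labels[int(rng.choice(len(labels), p=weights))]
            chrom, pos = pop_slot(label)
            length = _draw_length(config, rng)
            is_insertion = bool(rng.random() < 0.5)
            v = _make_variant(reference, chrom, pos, length, is_insertion, config.reference_id, rng)
            if v.key not in truth.variants:
                break
        else:  # pragma: no cover - would need pathological collision rates
            raise SimulationConfigError("could not place variant without key collision")
        truth.variants[v.key] = VariantTruth(origin, v.indel_length, label)
        if origin in ("maternal_specific", "shared"):
            maternal.add(v.with_zygosity(_draw_zygosity(config, rng, specific)))
        if origin in ("paternal_specific", "shared"):
            paternal.add(v.with_zygosity(_draw_zygosity(config, rng, specific)))
        if origin == "maternal_specific" and v.indel_length > 50:
            anchor = reference[chrom][v.position - 1]
            linked = InDelVariant(
                reference_id=config.reference_id,
                chromosome=v.chromosome,
                position=v.position,
                ref_allele=anchor,
                alt_allele=anchor + _random_insert(rng, LINKED_DIVERGENCE_BP),
            )
            linked = left_normalize(linked, reference)
            if linked.key in truth.variants:  # pragma: no cover
                continue
            truth.variants[linked.key] = VariantTruth(
                "paternal_linked", linked.indel_length, label, linked_to=v.key
            )
            truth.linked_paternal[v.key] = linked.key
            paternal.add(linked.with_zygosity(Zygosity.HOMOZYGOUS))
    return ParentSimulation(
        config=config,
        reference=reference,
        maternal_table=maternal,
        paternal_table=paternal,
        gene_models=models,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Progeny simulation


@dataclass
class ProgenySimulation:
    tables: list[VariantTable]
    truth: TruthLog

    @property
    def individual_ids(self) -> list[str]:
        return [t.sample_id for t in self.tables]


def _transmission_prob(zygosity: Zygosity, t: float) -> float:
    return t if zygosity is Zygosity.HETEROZYGOUS else 1.0


def _simulate_progeny_tables(
    maternal_table: VariantTable,
    paternal_table: VariantTable,
    n_progeny: int,
    hybrid_fraction: float,
    transmission_probability: float,
    dropout_rate: float,
    rng: np.random.Generator,
    truth: TruthLog,
    id_prefix: str = "F1",
) -> list[VariantTable]:
    n_hybrid = round(hybrid_fraction * n_progeny)
    classes = ["true_hybrid"] * n_hybrid + ["maternal_only"] * (n_progeny - n_hybrid)
    order = rng.permutation(n_progeny)
    classes = [classes[i] for i in order]
    m_variants = [maternal_table.get(k) for k in sorted(maternal_table.informative_keys())]
    p_variants = [paternal_table.get(k) for k in sorted(paternal_table.informative_keys())]
    t = transmission_probability
    tables = []
    for i in range(n_progeny):
        ind = f"{id_prefix}_{i + 1:03d}"
        cls = classes[i]
        truth.individual_class[ind] = cls
        table = VariantTable(ind, maternal_table.reference_id)
        carried: dict[VariantKey, Zygosity] = {}
        for v in m_variants:
            if rng.random() < _transmission_prob(v.zygosity, t):
                # a maternal-only individual is a doubled maternal gamete
                carried[v.key] = (
                    Zygosity.HOMOZYGOUS if cls == "maternal_only" else Zygosity.HETEROZYGOUS
                )
        if cls == "true_hybrid":
            for v in p_variants:
                if rng.random() < _transmission_prob(v.zygosity, t):
                    carried[v.key] = (
                        Zygosity.HOMOZYGOUS if v.key in carried else Zygosity.HETEROZYGOUS
                    )
        for key, zyg in carried.items():
            source = maternal_table.get(key) or paternal_table.get(key)
            if rng.random() < dropout_rate:
                table.add(source.with_zygosity(Zygosity.MISSING))
                truth.dropouts.add((key, ind))
            else:
                table.add(source.with_zygosity(zyg))
        tables.append(table)
    return tables


def simulate_progeny(parents: ParentSimulation, config: SimulationConfig | None = None) -> ProgenySimulation:
    """Mendelian progeny of the simulated parents, with dropout, plus truth."""
    config = config or parents.config
    rng = np.random.default_rng([config.seed, 1])
    tables = _simulate_progeny_tables(
        parents.maternal_table,
        parents.paternal_table,
        config.n_progeny,
        config.hybrid_fraction,
        config.transmission_probability,
        config.dropout_rate,
        rng,
        parents.truth,
    )
    return ProgenySimulation(tables=tables, truth=parents.truth)


# ---------------------------------------------------------------------------
# Validation (transferability) populations


@dataclass
class ValidationSimulation:
    population_id: str
    maternal_table: VariantTable
    paternal_table: VariantTable
    progeny_tables: list[VariantTable]
    lost_marker_ids: tuple[str, ...]
    truth: TruthLog


def _drop_keys(table: VariantTable, keys: set) -> VariantTable:
    out = VariantTable(table.sample_id, table.reference_id)
    for v in table:
        if v.key not in keys:
            out.add(v)
    return out


def simulate_validation_population(
    parents: ParentSimulation,
    markers: Sequence,
    config: SimulationConfig,
    population_id: str,
    n_f1: int,
    stream: int,
) -> ValidationSimulation:
    """A second cross sharing a ``marker_loss_fraction``-reduced marker set.

    Lost markers are made non-polymorphic by equalizing the parental alleles:
    the new maternal parent lacks the marker InDel and the new paternal
    parent lacks its linked divergence allele, so both parents would show the
    same reference band. Remaining markers segregate exactly as in
    :func:`simulate_progeny`, with the validation hybrid fraction.
    """
    rng = np.random.default_rng([config.seed, 2, stream])
    truth = TruthLog(
        variants=parents.truth.variants,
        linked_paternal=parents.truth.linked_paternal,
    )
    n_lost = round(config.marker_loss_fraction * len(markers))
    lost_idx = set(rng.choice(len(markers), size=n_lost, replace=False).tolist()) if n_lost else set()
    lost = [markers[i] for i in sorted(lost_idx)]
    lost_maternal_keys = {m.variant.key for m in lost}
    lost_paternal_keys = {
        parents.truth.linked_paternal[k]
        for k in lost_maternal_keys
        if k in parents.truth.linked_paternal
    }
    maternal = _drop_keys(parents.maternal_table, lost_maternal_keys)
    paternal = _drop_keys(parents.paternal_table, lost_paternal_keys)
    progeny = _simulate_progeny_tables(
        maternal,
        paternal,
        n_f1,
        config.hybrid_fraction_validation,
        config.transmission_probability,
        config.dropout_rate,
        rng,
        truth,
        id_prefix=f"{population_id}_F1",
    )
    return ValidationSimulation(
        population_id=population_id,
        maternal_table=maternal,
        paternal_table=paternal,
        progeny_tables=progeny,
        lost_marker_ids=tuple(m.marker_id for m in lost),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Whole-study convenience


@dataclass
class StudySimulation:
    parents: ParentSimulation
    progeny: ProgenySimulation

    @property
    def config(self) -> SimulationConfig:
        return self.parents.config

    @property
    def truth(self) -> TruthLog:
        return self.parents.truth

    def write(self, outdir: str) -> None:
        import os

        self.parents.write(outdir)
        write_population_vcf(
            self.progeny.tables,
            os.path.join(outdir, "progeny.vcf"),
            self.parents.contig_lengths(),
        )


def simulate_study(config: SimulationConfig) -> StudySimulation:
    parents = simulate_parents(config)
    progeny = simulate_progeny(parents, config)
    return StudySimulation(parents=parents, progeny=progeny)


# ---------------------------------------------------------------------------
# Emission


def write_fasta(reference: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_population_vcf(
    tables: Sequence[VariantTable],
    path: str,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Emit a multi-sample VCF v4.2 over the union of all tables' records."""
    gt_for = {
        Zygosity.HETEROZYGOUS: "0/1",
        Zygosity.HOMOZYGOUS: "1/1",
        Zygosity.MISSING: "./.",
    }
    all_keys: dict[VariantKey, tuple[str, str]] = {}
    for t in tables:
        for v in t:
            all_keys.setdefault(v.key, (v.ref_allele, v.alt_allele))
    contigs = contig_lengths or {}
    chroms = sorted({k[0] for k in all_keys} | set(contigs))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            if chrom in contigs:
                fh.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        sample_ids = [t.sample_id for t in tables]
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for key in sorted(all_keys):
            chrom, pos, ref, alt = key
            gts = []
            for t in tables:
                v = t.get(key)
                gts.append(gt_for[v.zygosity] if v is not None else "0/0")
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
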