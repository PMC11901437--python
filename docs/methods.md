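# Methods

## Problem and model

The package authenticates progeny of a distant (interspecific) cross in
which offspring phenotypes converge on the maternal parent. The unit of
evidence is a codominant InDel marker: a locus where the two parents
contribute PCR amplicons of distinguishable size, so a true hybrid shows two
bands (one per parental allele) and a maternal-only individual shows at most
the maternal band. The analysis operates entirely downstream of variant
calling: its inputs are per-sample InDel call sets (VCF) in a single
reference frame, gene models (GFF3) and the reference sequence (FASTA).

Variant identity is the exact key (chromosome, position, REF, ALT) after
left-normalization. No fuzzy positional matching is attempted: all call sets
are assumed to come from one caller against one assembly, where identical
events normalize to identical keys, and positional tolerance would inflate
apparent parent-specificity. Left-alignment follows the standard algorithm
(trim shared trailing bases, extending leftward across repeats; trim shared
leading bases beyond the anchor); an InDel that shifts all the way to the
contig start is anchored on the right, matching `bcftools norm`, against
which the implementation is cross-checked in the test suite.

A parental genotype of 0/0 at a site means the sample does not carry the
variant, so such records are excluded from that sample's table. Missing
genotypes (./.) are retained with a `missing` zygosity but count as absence
in all presence logic, because a missing call is indistinguishable from low
coverage; parent-specific calls whose counterpart was missing (rather than
absent) in the other parent carry an `other_parent_missing` flag.

## Marker funnel

1. **Specificity.** Maternal-specific = informative maternal keys minus
   informative paternal keys (symmetric for paternal). Sets are provably
   disjoint.
2. **Length.** Strictly greater than 50 bp, so the allelic amplicons are
   resolvable on a 2.0% agarose gel; a 50 bp InDel is excluded.
3. **Offspring coverage.** Fraction of *all* supplied progeny whose call set
   informatively contains the same key, strictly greater than 50%. The
   denominator is the full progeny count, not the callable subset, matching
   the definition of coverage as a fraction of offspring individuals; a
   secondary callable-only rate is reported separately in genotyping
   statistics.

Candidates are ordered by (chromosome, position) and named
`InDel{chromosome}-{rank within chromosome}`.

## In-silico PCR and genotype calls

Primers are exact 20-mers at the two ends of a marker's target region
(default flank 200 bp around the InDel). Matching is exact string search;
thermodynamics, mismatches and PCR failure modes are out of scope. Amplicon
size uses the 5'-start to 5'-start inclusive convention on the plus strand;
the only size property relied on downstream — the difference between the two
allelic amplicons equals the InDel length — is convention-independent.
Products over 3,000 bp or with a missing primer site contribute no band;
more than one exact site for a primer on a haplotype is an error. Bands
closer than the gel resolution (default 20 bp, conservative for 2.0%
agarose) merge to the larger size; merging is single-linkage over sorted
sizes and therefore order-independent.

Per-individual haplotypes for a marker apply exactly two alleles: the marker
InDel (maternal origin) when the individual's call set carries it, and the
linked paternal allele — the *paternal-specific* informative call nearest
the marker position and fully contained in the target region — when carried.
Paternal-specificity of the linked allele is essential: an allele the mother
also carries reaches maternal-only offspring and would produce two-band
false positives. Other variation inside
the amplicon is not applied; this is the usual in-silico PCR assumption that
a usable primer target is free of interfering variation (markers violating
it in the wet lab are the ones that fail the polymorphism screen).

Genotype calls per (marker, individual) require each parent to show a single
band and the parental bands to differ by at least the gel resolution;
markers failing this are non-polymorphic, flagged, and their cells reported
as missing. Band matching against parental sizes is exact:
`both_parents` / `maternal_only` / `paternal_only` / `ambiguous` (no
parental size present) / `missing` (no bands). An individual is a true
hybrid iff at least one marker call is `both_parents` (per-marker scoring,
OR aggregation); an individual with zero valid calls is `undetermined`,
distinct from "not identified".

## Panel selection

Minimal-panel choice is set cover over the per-marker identified sets. The
default solver is greedy max coverage: repeatedly add the marker covering
the most not-yet-identified individuals, breaking ties by higher
single-marker count and then lexicographically smaller marker ID, so results
are deterministic; coverage at fixed panel size k is at least (1 − 1/e) of
the optimum. An exhaustive solver (bitmask unions over subsets, smallest
cardinality first, lexicographically smallest among equals) serves as an
oracle up to 20 markers and refuses larger instances.

Transferability of a reference panel to a new population tracks two
conditions separately: parental polymorphism in the new cross, and
informativeness (at least one `both_parents` call). A marker is *effective*
only if both hold; universality = effective / total reference markers, and
the hybrid rate = individuals with ≥ 1 `both_parents` call over effective
markers / all F1. All headline percentages are rounded half-up to one
decimal.

## Synthetic data: what it emulates

The simulator generates the statistical structure the pipeline assumes, at
desk scale, with complete truth logs (per-variant provenance and region
label, per-individual class, per-cell dropout) and byte-reproducible output
from a single seed.

Defaults (the study conditions): 17 chromosomes × 200 kb; 2,000 parental
InDels per frame, 20% parent-specific; InDel lengths a two-component mixture
(1–10 bp short, 51–120 bp long) with 30% long mass; 62 progeny, all true
hybrids in the discovery population; transmission probability 0.5
(parent-specific InDels planted heterozygous); dropout 0.1 per (site,
individual); three validation populations of 46, 76 and 40 progeny with 85%
true hybrids and 20% marker loss. The genome-scale totals of a real
resequencing study (~1.5 M InDels, thousands of specific calls) are not
reproducible from scratch at desk size; the desk-scale parameters are chosen
so every funnel stage, the ~50% per-marker identification regime, the
100%-by-union panel and the transferability contrast are all exercised in
seconds. The long-length mass (30% versus ~1% in genome-scale data) is
deliberately enriched so that tens of marker-eligible loci exist among a few
hundred specific calls; it changes stage proportions, not the logic any
stage applies.

Modelling choices that matter:

* **Heterozygous planting.** Parent-specific markers are heterozygous in
  their parent by default, so each transmits to ~half the progeny. This is
  what produces per-marker identification rates near 50% and makes combined
  panels necessary — the observed regime in real apple × pear data.
  Homozygous planting (`specific_zygosity="homozygous"`, transmission 1) is
  the perfect-detection scenario switch.
* **Linked paternal divergence.** Every long maternal-specific InDel gets a
  homozygous paternal +30 bp insertion at the same site (its own VCF
  record). Two species' haplotypes differ at essentially any locus; this
  divergence is what makes the marker codominant, giving the paternal allele
  a band distinct from both maternal alleles. Without it the paternal band
  would equal the reference band and could not separate hybrids from
  reference-allele carriers.
* **Maternal-only progeny** (pollen failure or selfing-like origins,
  deliberately not distinguished) are a doubled single maternal gamete:
  homozygous at every carried site, never showing two distinct alleles at a
  marker, hence never falsely called hybrid under exact band matching.
* **Dropout** erases a carried call into a missing genotype (./.) per site
  per individual, independently.
* **Validation populations** reuse the discovery parents with a fraction of
  markers made non-polymorphic by equalizing parental alleles (the new
  mother lacks the marker InDel, the new father its linked allele);
  remaining markers segregate as in the discovery cross.

Closed forms used in testing: offspring coverage of a heterozygous
parent-specific marker has mean t(1 − d) (0.45 at defaults) over all progeny
carrying that parent's material — h·t(1 − d) for paternal-specific markers
when only a fraction h of progeny are hybrids; per-marker hybrid detection is
p = t(1 − d)², and panel sensitivity is 1 − (1 − p)^k. These are verified
within binomial confidence bounds. Sensitivity and transmission-recovery
checks deliberately avoid markers chosen by the coverage filter inside the
same cohort (or use an independent validation cohort): coverage selection
conditions on high in-sample transmission and biases per-marker rates upward.

What passing tests do *not* show about real data: no read-level error model,
no mapping or calling bias between reference frames (real dual-frame calls
differ systematically), no primer thermodynamic failures (real marker panels
lose ~half their primer pairs to amplification and polymorphism screens),
uniform rather than clustered InDel placement, and a single simple gene
template rather than real gene architecture. The simulator validates the
pipeline's logic and statistics, not variant-calling accuracy.

## Numerical and degenerate-input conventions

* Percentages: decimal half-up rounding to one decimal (35/62 → 56.5).
* Both funnel thresholds strict (>): a 50 bp or exactly-50%-coverage marker
  is excluded.
* Multi-allelic VCF records are decomposed per ALT before normalization;
  duplicate keys after normalization keep the first record.
* Empty progeny list: coverage is undefined and an error, raised before any
  computation.
* Empty tables summarize to all-zero counts; empty marker lists give
  all-zero chromosome distributions; a population where no marker is
  effective reports universality 0% with zero identified hybrids.
* The exhaustive panel solver refuses > 20 markers and directs callers to
  the greedy solver.
* Region annotation is anchored at the variant's (left-normalized) anchor
  base; precedence splicing > UTR > exon > intron > upstream > downstream >
  intergenic, with splicing defined as within 2 bp of an internal
  exon–intron boundary and upstream/downstream as strand-aware 1 kb windows.

## Known limitations

* Variant matching across samples requires a shared caller and frame; calls
  lifted between assemblies will not match by key.
* The two-band rule cannot detect hybrids at markers whose maternal allele
  failed to transmit; identification is inherently probabilistic per marker,
  which is why panels are unions.
* Phase is taken from parental origin when building haplotypes, which is
  exact in simulation but an approximation for real unphased calls.
* `ambiguous` bands (matching neither parent) are reported as their own
  category rather than folded into either class; real novel bands would
  need wet-lab follow-up.
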