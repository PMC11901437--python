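"""In-silico PCR: amplicons, gel resolution, genotype and hybrid calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indelmark import (
    BandPattern,
    GenotypeCall,
    PrimerPair,
    call_hybrid,
    genotype_individual,
    predict_amplicons,
    resolve_bands,
)
from indelmark.pcr import AmbiguousPrimerError, MarkerInvalidError, revcomp


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _primers(region, length=20, marker_id="M1"):
    return PrimerPair(marker_id, region[:length], revcomp(region[-length:]))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(42)


def _pattern(*bands, marker_id="M1", individual_id="X"):
    return BandPattern(marker_id, individual_id, frozenset(bands))


class TestPredictAmplicons:
    def test_identical_haplotypes_single_band(self, rng):
        region = _rand_seq(rng, 300)
        pattern = predict_amplicons(_primers(region), [region, region])
        assert pattern.bands == frozenset({300})

    def test_insertion_shifts_band_by_indel_length(self, rng):
        region = _rand_seq(rng, 300)
        with_ins = region[:150] + _rand_seq(rng, 76) + region[150:]
        pattern = predict_amplicons(_primers(region), [region, with_ins])
        assert pattern.bands == frozenset({300, 376})

    def test_no_binding_site_gives_no_band(self, rng):
        region = _rand_seq(rng, 300)
        other = _rand_seq(rng, 300)
        pattern = predict_amplicons(_primers(region), [other])
        assert pattern.bands == frozenset()

    def test_duplicate_site_is_ambiguous(self, rng):
        region = _rand_seq(rng, 200)
        doubled = region[:20] + region  # forward site twice
        with pytest.raises(AmbiguousPrimerError):
            predict_amplicons(_primers(region), [doubled])

    def test_oversized_product_does_not_amplify(self, rng):
        region = _rand_seq(rng, 300)
        stretched = region[:150] + _rand_seq(rng, 4000) + region[150:]
        pattern = predict_amplicons(_primers(region), [stretched])
        assert pattern.bands == frozenset()

    def test_band_difference_equals_planted_length_across_markers(self, study, genotyped):
        """For every simulated marker, the two allelic amplicons differ by
        exactly the planted InDel length."""
        from indelmark.pipeline import apply_allele

        matrix, primers = genotyped
        checked = 0
        for marker in _markers(study):
            chrom, start, end = marker.target_region
            region = study.parents.reference[chrom][start - 1 : end]
            hap_alt = apply_allele(region, start, marker.variant)
            pattern = predict_amplicons(primers[marker.marker_id], [region, hap_alt])
            sizes = sorted(pattern.bands)
            assert sizes[1] - sizes[0] == marker.variant.indel_length
            checked += 1
        assert checked >= 3


def _markers(study):
    from indelmark import discover

    return discover(
        study.parents.maternal_table, study.parents.paternal_table, study.progeny.tables
    ).markers


class TestResolveBands:
    def test_close_bands_merge_to_larger(self):
        assert resolve_bands(_pattern(300, 310)).bands == frozenset({310})

    def test_separated_bands_unchanged(self):
        assert resolve_bands(_pattern(300, 376)).bands == frozenset({300, 376})

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        sizes=st.sets(st.integers(100, 600), min_size=1, max_size=2),
        resolution=st.sampled_from([10, 20, 40]),
    )
    def test_merge_is_idempotent_and_order_free(self, sizes, resolution):
        p = BandPattern("M1", "X", frozenset(sizes))
        once = resolve_bands(p, resolution)
        assert resolve_bands(once, resolution).bands == once.bands
        assert max(once.bands) == max(sizes)

    def test_marker_scale_differences_survive_gel_resolution(self, study, genotyped):
        """All markers pass the >50 bp filter, so their allelic bands remain
        distinct after the 20 bp agarose merge."""
        from indelmark.pipeline import apply_allele

        _, primers = genotyped
        for marker in _markers(study):
            chrom, start, end = marker.target_region
            region = study.parents.reference[chrom][start - 1 : end]
            hap_alt = apply_allele(region, start, marker.variant)
            pattern = resolve_bands(
                predict_amplicons(primers[marker.marker_id], [region, hap_alt])
            )
            assert len(pattern.bands) == 2


class TestGenotypeIndividual:
    M = _pattern(376, individual_id="mother")
    P = _pattern(330, individual_id="father")

    @pytest.mark.parametrize(
        "bands,expected",
        [
            ({376, 330}, GenotypeCall.BOTH_PARENTS),
            ({376}, GenotypeCall.MATERNAL_ONLY),
            ({330}, GenotypeCall.PATERNAL_ONLY),
            ({300}, GenotypeCall.AMBIGUOUS),
            (set(), GenotypeCall.MISSING),
        ],
    )
    def test_call_classes(self, bands, expected):
        assert genotype_individual(_pattern(*bands), self.M, self.P) is expected

    def test_nonpolymorphic_parents_invalid(self):
        with pytest.raises(MarkerInvalidError):
            genotype_individual(_pattern(376), self.M, _pattern(376))
        with pytest.raises(MarkerInvalidError):
            genotype_individual(_pattern(376), _pattern(300, 376), self.P)


class TestCallHybrid:
    def test_one_both_parents_call_suffices(self):
        calls = {f"M{i}": GenotypeCall.MATERNAL_ONLY for i in range(50)}
        calls["M50"] = GenotypeCall.BOTH_PARENTS
        result = call_hybrid(calls, "X")
        assert result.is_true_hybrid and result.supporting_markers == ("M50",)

    def test_all_maternal_only_is_not_hybrid(self):
        result = call_hybrid({"M1": GenotypeCall.MATERNAL_ONLY}, "X")
        assert not result.is_true_hybrid and result.determined

    def test_no_valid_calls_is_undetermined(self):
        result = call_hybrid({"M1": GenotypeCall.MISSING}, "X")
        assert not result.determined and not result.is_true_hybrid

    def test_invariant_to_marker_order_and_extra_maternal_calls(self):
        base = {"M2": GenotypeCall.BOTH_PARENTS, "M1": GenotypeCall.AMBIGUOUS}
        extra = dict(base)
        extra.update({f"N{i}": GenotypeCall.MATERNAL_ONLY for i in range(5)})
        a = call_hybrid(base, "X")
        b = call_hybrid(dict(reversed(list(extra.items()))), "X")
        assert a.is_true_hybrid == b.is_true_hybrid == True  # noqa: E712
        assert a.supporting_markers == b.supporting_markers

    def test_sensitivity_matches_closed_form(self, study, small_config):
        """P(hybrid called by a size-k panel) = 1 - (1-p)^k with per-marker
        detection p = t(1-d)^2: the marker allele transmits with probability
        t and survives dropout, and the linked paternal allele (homozygous,
        always transmitted) survives dropout independently.

        Computed on all length-passing markers WITHOUT the coverage filter:
        coverage selection would bias per-marker rates upward in-sample.
        """
        from indelmark import call_parent_specific, offspring_coverage, select_candidates
        from indelmark.pipeline import genotype_population

        m_spec, _ = call_parent_specific(
            study.parents.maternal_table, study.parents.paternal_table
        )
        filled = offspring_coverage(m_spec, study.progeny.tables)
        markers = select_candidates(filled, min_length=50, min_coverage=0.0)
        matrix, _ = genotype_population(
            study.parents.reference,
            markers,
            study.parents.maternal_table,
            study.parents.paternal_table,
            study.progeny.tables,
        )
        t, d = small_config.transmission_probability, small_config.dropout_rate
        p = t * (1 - d) ** 2
        hybrids = study.truth.hybrids()
        marker_ids = matrix.markers
        for k in (1, 3, len(marker_ids)):
            sub = matrix.calls.loc[marker_ids[:k], hybrids]
            called = sum(
                call_hybrid(
                    {m: GenotypeCall(sub[ind][m]) for m in sub.index}, ind
                ).is_true_hybrid
                for ind in hybrids
            ) / len(hybrids)
            expected = 1 - (1 - p) ** k
            se = np.sqrt(expected * (1 - expected) / len(hybrids))
            assert abs(called - expected) < 4 * max(se, 0.01), (k, called, expected)
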