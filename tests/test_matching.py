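"""Allele-concordance classification, strand-flip logic and flip policy."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pgsapply import (
    MatchCategory,
    PolicyError,
    apply_flip_policy,
    assess_allele_match,
    combine_vcf_with_pgs,
    import_pgs_weight_file,
    import_vcf,
    is_palindromic,
    match_report_frame,
    reverse_complement,
)
from pgsapply.vcf import VcfSite
from pgsapply.weights import PGSModel, WeightEntry

from _helpers import vcf_record, write_vcf, write_weights

BASES = "ACGT"


def _weight(ea, oa, **kw):
    defaults = dict(variant_id="v", chrom="1", pos=100, beta=0.5)
    defaults.update(kw)
    return WeightEntry(effect_allele=ea, other_allele=oa, **defaults)


def _site(ref, alts):
    return VcfSite(chrom="1", pos=100, ref=ref, alts=tuple(alts))


class TestPrimitives:
    @pytest.mark.parametrize("allele, rc", [("A", "T"), ("AG", "CT"), ("GATC", "GATC")])
    def test_reverse_complement(self, allele, rc):
        assert reverse_complement(allele) == rc

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet=BASES, min_size=1, max_size=12))
    def test_reverse_complement_involution(self, allele):
        assert reverse_complement(reverse_complement(allele)) == allele

    def test_reverse_complement_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            reverse_complement("AN")

    @pytest.mark.parametrize(
        "a1, a2, expected",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("A", "G", False),
         ("A", "C", False), ("G", "T", False)],
    )
    def test_is_palindromic(self, a1, a2, expected):
        assert is_palindromic(a1, a2) is expected


class TestAssessAlleleMatch:
    @pytest.mark.parametrize(
        "ea, oa, ref, alts, expected",
        [
            # effect allele reported relative to the VCF reference allele
            ("A", "G", "A", ["G"], MatchCategory.EFFECT_SWITCH),
            # palindromic pair: strand flip indistinguishable from effect flip
            ("A", "T", "A", ["T"], MatchCategory.AMBIGUOUS_FLIP),
            ("C", "G", "G", ["C"], MatchCategory.AMBIGUOUS_FLIP),
            # plain concordance, effect allele is an ALT
            ("G", "A", "A", ["G"], MatchCategory.DEFAULT_MATCH),
            # only consistent after complementing both model alleles
            ("C", "T", "A", ["G"], MatchCategory.STRAND_FLIP),
            ("G", "A", "C", ["T"], MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP),
            # no assignment works (direct and complemented checks both fail)
            ("A", "G", "A", ["C"], MatchCategory.MISMATCH),
            # multiallelic: effect and other both among site alleles
            ("C", "A", "A", ["G", "C"], MatchCategory.DEFAULT_MATCH),
        ],
    )
    def test_decision_table(self, ea, oa, ref, alts, expected):
        assert assess_allele_match(_weight(ea, oa), _site(ref, alts)) == expected

    @pytest.mark.parametrize(
        "ea, oa, ref, alts, expected",
        [
            ("AT", "A", "A", ["AT"], MatchCategory.INDEL),
            ("A", "AT", "AT", ["A"], MatchCategory.INDEL),
            ("AT", "A", "C", ["G"], MatchCategory.MISMATCH),
            # indels are matched literally, never complemented
            ("AT", "A", "TA", ["T"], MatchCategory.MISMATCH),
            # site carries an indel allele: literal matching applies too
            ("G", "A", "A", ["G", "AT"], MatchCategory.INDEL),
        ],
    )
    def test_indel_rules(self, ea, oa, ref, alts, expected):
        assert assess_allele_match(_weight(ea, oa), _site(ref, alts)) == expected

    @pytest.mark.parametrize(
        "ea, ref, alts, expected",
        [
            ("A", "A", ["G"], MatchCategory.EFFECT_SWITCH),
            ("G", "A", ["G"], MatchCategory.DEFAULT_MATCH),
            ("C", "A", ["G"], MatchCategory.MISMATCH),  # no strand detection
        ],
    )
    def test_missing_other_allele_downgrades_detection(self, ea, ref, alts, expected):
        assert assess_allele_match(_weight(ea, None), _site(ref, alts)) == expected

    def test_orientation_symmetry(self):
        """Swapping effect/other converts default<->switch and flip<->both."""
        for ea, oa in itertools.permutations(BASES, 2):
            if is_palindromic(ea, oa):
                continue
            for ref, alt in itertools.permutations(BASES, 2):
                if is_palindromic(ref, alt):
                    continue
                site = _site(ref, [alt])
                cat = assess_allele_match(_weight(ea, oa), site)
                swapped = assess_allele_match(_weight(oa, ea), site)
                pairs = {
                    MatchCategory.DEFAULT_MATCH: MatchCategory.EFFECT_SWITCH,
                    MatchCategory.EFFECT_SWITCH: MatchCategory.DEFAULT_MATCH,
                    MatchCategory.STRAND_FLIP: MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP,
                    MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP: MatchCategory.STRAND_FLIP,
                }
                assert swapped == pairs.get(cat, cat)

    def test_complement_symmetry(self):
        """Complementing both model alleles converts default_match <-> strand_flip."""
        for ea, oa in itertools.permutations(BASES, 2):
            if is_palindromic(ea, oa):
                continue
            for ref, alt in itertools.permutations(BASES, 2):
                if is_palindromic(ref, alt):
                    continue
                site = _site(ref, [alt])
                cat = assess_allele_match(_weight(ea, oa), site)
                comp = assess_allele_match(
                    _weight(reverse_complement(ea), reverse_complement(oa)), site
                )
                pairs = {
                    MatchCategory.DEFAULT_MATCH: MatchCategory.STRAND_FLIP,
                    MatchCategory.STRAND_FLIP: MatchCategory.DEFAULT_MATCH,
                    MatchCategory.EFFECT_SWITCH: MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP,
                    MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP: MatchCategory.EFFECT_SWITCH,
                }
                assert comp == pairs.get(cat, cat)

    def _oracle(self, ea, oa, ref, alt):
        """Enumerate orientation/complement assignments as set comparisons."""
        site = {ref, alt}
        if {ea, oa} in ({"A", "T"}, {"C", "G"}):
            return (
                MatchCategory.AMBIGUOUS_FLIP if {ea, oa} == site else MatchCategory.MISMATCH
            )
        for flipped in (False, True):
            e = reverse_complement(ea) if flipped else ea
            o = reverse_complement(oa) if flipped else oa
            if {e, o} == site:
                if e == ref and not flipped:
                    return MatchCategory.EFFECT_SWITCH
                if e != ref and not flipped:
                    return MatchCategory.DEFAULT_MATCH
                if e == ref:
                    return MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP
                return MatchCategory.STRAND_FLIP
        return MatchCategory.MISMATCH

    def test_agrees_with_enumeration_oracle_on_all_biallelic_configs(self):
        for ea, oa in itertools.permutations(BASES, 2):
            for ref, alt in itertools.permutations(BASES, 2):
                got = assess_allele_match(_weight(ea, oa), _site(ref, [alt]))
                assert got == self._oracle(ea, oa, ref, alt), (ea, oa, ref, alt)


class TestCombine:
    def _inputs(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf",
            [
                vcf_record("1", 100, "A", "G", ["0/1"]),
                vcf_record("1", 200, "C", "T", ["1/1"]),
            ],
            ["s1"],
        )
        weights = write_weights(
            tmp_path / "w.txt",
            [
                {"rsID": "r1", "chr_name": "1", "chr_position": 100,
                 "effect_allele": "G", "other_allele": "A", "effect_weight": 0.1},
                {"rsID": "r2", "chr_name": "1", "chr_position": 200,
                 "effect_allele": "T", "other_allele": "C", "effect_weight": 0.2},
                {"rsID": "r3", "chr_name": "1", "chr_position": 999,
                 "effect_allele": "A", "other_allele": "G", "effect_weight": 0.3},
            ],
        )
        return import_vcf(vcf), import_pgs_weight_file(weights)

    def test_missing_sites_reported(self, tmp_path):
        genotypes, model = self._inputs(tmp_path)
        merged, missing = combine_vcf_with_pgs(genotypes, model)
        assert len(merged) == 3
        assert [m.category for m in merged] == [
            MatchCategory.DEFAULT_MATCH,
            MatchCategory.DEFAULT_MATCH,
            MatchCategory.MISSING_SITE,
        ]
        assert [w.variant_id for w in missing] == ["r3"]

    def test_category_partition_sums_to_model_size(self, tmp_path):
        genotypes, model = self._inputs(tmp_path)
        merged, _ = combine_vcf_with_pgs(genotypes, model)
        report = match_report_frame(merged)
        assert report["category"].value_counts().sum() == model.n_variants

    def test_two_model_entries_one_multiallelic_site(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "m.vcf", [vcf_record("1", 100, "A", "G,C", ["1/2"])], ["s1"]
        )
        entries = [
            WeightEntry("a", "1", 100, "G", "A", 0.1),
            WeightEntry("b", "1", 100, "C", "A", 0.2),
        ]
        merged, missing = combine_vcf_with_pgs(import_vcf(vcf), PGSModel(entries=entries))
        assert not missing
        assert [m.effect_allele_index for m in merged] == [1, 2]

    def test_chr_prefix_insensitive_join(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "t.vcf", [vcf_record("chr1", 100, "A", "G", ["0/1"])], ["s1"]
        )
        model = PGSModel(entries=[WeightEntry("r1", "1", 100, "G", "A", 0.1)])
        merged, missing = combine_vcf_with_pgs(import_vcf(vcf), model)
        assert not missing and merged[0].category == MatchCategory.DEFAULT_MATCH


class TestFlipPolicy:
    @staticmethod
    def _merged(categories):
        from pgsapply.matching import MergedVariant

        out = []
        for i, cat in enumerate(categories):
            if cat == MatchCategory.AMBIGUOUS_FLIP:
                weight, site, idx = _weight("A", "T", variant_id=f"v{i}"), _site("A", ["T"]), 0
            elif cat in (
                MatchCategory.STRAND_FLIP,
                MatchCategory.EFFECT_SWITCH_WITH_STRAND_FLIP,
            ):
                weight, site, idx = _weight("C", "T", variant_id=f"v{i}"), _site("A", ["G"]), None
            else:  # default_match
                weight, site, idx = _weight("G", "A", variant_id=f"v{i}"), _site("A", ["G"]), 1
            out.append(
                MergedVariant(
                    weight=weight, site=site, site_idx=0, category=cat,
                    effect_allele_index=idx,
                )
            )
        return out

    def test_zero_flips_passes_zero_threshold(self):
        merged = self._merged([MatchCategory.DEFAULT_MATCH] * 3)
        annotated, report = apply_flip_policy(merged, max_strand_flips=0)
        assert report["n_strand_flips"] == 0 and len(annotated) == 3

    def test_threshold_exceeded_reports_counts(self):
        merged = self._merged([MatchCategory.STRAND_FLIP] * 3)
        with pytest.raises(PolicyError, match="3"):
            apply_flip_policy(merged, max_strand_flips=2)

    def test_remove_ambiguous_shrinks_scored_set(self):
        merged = self._merged(
            [MatchCategory.AMBIGUOUS_FLIP] * 2 + [MatchCategory.DEFAULT_MATCH] * 3
        )
        annotated, report = apply_flip_policy(merged, remove_ambiguous=True)
        assert report["n_scoreable"] == 3
        assert report["removed_ambiguous"] == ["v0", "v1"]

    def test_correct_strand_flips_assigns_complemented_index(self):
        merged = self._merged([MatchCategory.STRAND_FLIP])
        annotated, _ = apply_flip_policy(
            merged, max_strand_flips=1, correct_strand_flips=True
        )
        # effect C complements to G == ALT at index 1
        assert annotated[0].effect_allele_index == 1

    def test_uncorrected_flips_not_scored(self):
        merged = self._merged([MatchCategory.STRAND_FLIP])
        annotated, report = apply_flip_policy(merged, max_strand_flips=1)
        assert annotated[0].effect_allele_index is None
        assert report["n_scoreable"] == 0
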