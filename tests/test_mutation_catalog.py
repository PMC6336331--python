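"""Somatic filtering, 96-channel classification, and pair-notation spectra."""

import numpy as np
import pytest

from premasig import (
    CHANNELS,
    PAIR_CATEGORIES,
    MutationRecord,
    SomaticFilterConfig,
    build_catalog96,
    build_pair_spectrum,
    classify_channel,
    filter_somatic,
    is_cpg,
    mutation_rate_per_mb,
    panel_summary,
    spectrum_compare,
    to_pair_notation,
)
from premasig.mutation_catalog import _COMPLEMENT, BASES

from conftest import enumeration_fisher_2x2


def rec(sample="case1", pos=100, ref="C", alt="A", source="tumor_dup1",
        vaf=0.10, effect="non-synonymous", gene=None):
    return MutationRecord(sample_id=sample, chrom="chr1", pos=pos, ref=ref,
                          alt=alt, gene=gene, effect=effect, vaf=vaf, source=source)


class TestChannelClassification:
    @pytest.mark.parametrize(
        "args,index",
        [
            (("C", "A", "A", "A"), 0),    # A[C>A]A, first channel
            (("T", "G", "T", "T"), 95),   # T[T>G]T, last channel
            (("G", "T", "A", "C"), 11),   # 5'-AGC-3' with G>T -> G[C>A]T
        ],
    )
    def test_known_channels(self, args, index):
        assert classify_channel(*args) == index

    def test_channel_labels_match_indices(self):
        assert CHANNELS[0] == "A[C>A]A"
        assert CHANNELS[95] == "T[T>G]T"
        assert CHANNELS[11] == "G[C>A]T"

    def test_strand_invariance_exhaustive(self):
        """Reverse-complementing the substitution and its context never
        changes the channel, over all 192 raw combinations."""
        pyrimidine_subs = [("C", a) for a in "AGT"] + [("T", a) for a in "ACG"]
        raw = []
        for ref, alt in pyrimidine_subs:
            for five in BASES:
                for three in BASES:
                    raw.append((ref, alt, five, three))
                    raw.append((_COMPLEMENT[ref], _COMPLEMENT[alt],
                                _COMPLEMENT[three], _COMPLEMENT[five]))
        assert len(raw) == 192  # 12 substitutions x 16 contexts
        for ref, alt, five, three in raw:
            fwd = classify_channel(ref, alt, five, three)
            rev = classify_channel(_COMPLEMENT[ref], _COMPLEMENT[alt],
                                   _COMPLEMENT[three], _COMPLEMENT[five])
            assert fwd == rev

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            classify_channel("C", "A", "N", "A")

    def test_indel_rejected(self):
        with pytest.raises(ValueError):
            classify_channel("CT", "C", "A", "A")


class TestPairNotation:
    @pytest.mark.parametrize(
        "ref,alt,label",
        [
            ("G", "T", "G:C>T:A"),
            ("C", "A", "G:C>T:A"),  # strand equivalence
            ("T", "C", "A:T>G:C"),
            ("C", "G", "G:C>C:G"),
            ("A", "T", "A:T>T:A"),
        ],
    )
    def test_labels(self, ref, alt, label):
        assert to_pair_notation(ref, alt) == label

    def test_indel_routed_upstream(self):
        with pytest.raises(ValueError):
            to_pair_notation("AT", "A")

    @pytest.mark.parametrize(
        "args,expected",
        [
            (("C", "T", "A", "G"), True),
            (("G", "A", "C", "T"), True),   # purine strand of a CpG C>T
            (("C", "T", "A", "A"), False),
            (("T", "C", "A", "G"), False),  # not a C reference after collapse
        ],
    )
    def test_is_cpg(self, args, expected):
        assert is_cpg(*args) is expected


class TestSomaticFilter:
    def base_pair(self, **kw):
        """A concordant duplicate call that passes every rule."""
        return [rec(source="tumor_dup1", **kw), rec(source="tumor_dup2", **kw)]

    def test_concordant_variant_retained(self):
        kept = filter_somatic(self.base_pair())
        assert len(kept) == 1 and kept[0].source == "tumor_dup1"

    def test_single_duplicate_dropped(self):
        records = self.base_pair() + [rec(pos=200, source="tumor_dup1")]
        kept = filter_somatic(records)
        assert {r.pos for r in kept} == {100}

    def test_blood_presence_drops_cohort_wide(self):
        # the blood hit belongs to another case but still vetoes the variant
        records = self.base_pair() + [rec(sample="case2", source="blood", vaf=0.5)]
        records += [rec(sample="case2", pos=300, source="tumor_dup1"),
                    rec(sample="case2", pos=300, source="tumor_dup2")]
        kept = filter_somatic(records)
        assert {(r.sample_id, r.pos) for r in kept} == {("case2", 300)}

    def test_population_af_above_threshold_dropped(self):
        kept = filter_somatic(self.base_pair(), pop_af={("chr1", 100, "C", "A"): 0.005})
        assert kept == []

    def test_population_af_at_threshold_retained(self):
        kept = filter_somatic(self.base_pair(), pop_af={("chr1", 100, "C", "A"): 0.001})
        assert len(kept) == 1

    def test_low_vaf_in_one_duplicate_dropped(self):
        records = [rec(source="tumor_dup1", vaf=0.10), rec(source="tumor_dup2", vaf=0.03)]
        assert filter_somatic(records) == []

    def test_effect_class_filter(self):
        records = self.base_pair(effect="synonymous")
        assert filter_somatic(records) == []

    def test_single_tumor_source_errors_with_case_name(self):
        with pytest.raises(ValueError, match="case1"):
            filter_somatic([rec(source="tumor_dup1")])

    def test_sequenced_sources_resolves_missing_duplicate(self):
        # dup2 was sequenced but clean: no error, variant still dropped
        kept = filter_somatic(
            [rec(source="tumor_dup1")],
            sequenced_sources={"case1": {"tumor_dup1", "tumor_dup2"}},
        )
        assert kept == []

    def test_idempotent_on_retained_output(self):
        """Re-filtering retained calls changes nothing (the duplicate-
        concordance rule is consumed by the first pass, so the second runs
        on the deduplicated single-source records)."""
        records = self.base_pair() + self.base_pair(pos=200) + [
            rec(pos=300, source="tumor_dup1")
        ]
        kept = filter_somatic(records)
        cfg2 = SomaticFilterConfig(require_both_duplicates=False)
        again = filter_somatic(kept, cfg2)
        assert again == kept
        assert filter_somatic(again, cfg2) == again


class TestCatalog:
    def test_empty_input(self):
        cat, other = build_catalog96([], {"chr1": "ACGT"})
        assert cat.counts.shape == (96, 0) and other == {}

    def test_single_snv(self):
        reference = {"chr1": "ACA" + "A" * 10}
        cat, other = build_catalog96([rec(pos=2, ref="C", alt="A")], reference)
        assert cat.counts[0, 0] == 1 and cat.counts.sum() == 1

    def test_out_of_contig_errors(self):
        with pytest.raises(ValueError, match="chr1"):
            build_catalog96([rec(pos=100)], {"chr1": "ACGT"})

    def test_column_sums_equal_snv_tallies(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        reference = {"chr1": seq}
        records = []
        for i in range(80):
            pos = int(rng.integers(2, 499))
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            records.append(rec(sample=f"s{i % 3}", pos=pos, ref=ref, alt=alt))
        records.append(rec(sample="s0", pos=2, ref=seq[1] + seq[2], alt=seq[1]))
        cat, other = build_catalog96(records, reference)
        direct = {s: sum(1 for r in records if r.sample_id == s and r.is_snv)
                  for s in cat.samples}
        for j, s in enumerate(cat.samples):
            assert cat.counts[:, j].sum() == direct[s]
        assert other["s0"] == 1

    def test_concatenation_block_structure(self):
        """Building a catalog over two cohorts equals the column-block join
        of the per-cohort catalogs."""
        reference = {"chr1": "AACATGA"}
        part1 = [rec(sample="a", pos=3, ref="C", alt="T")]
        part2 = [rec(sample="b", pos=5, ref="T", alt="G")]
        joint, _ = build_catalog96(part1 + part2, reference)
        c1, _ = build_catalog96(part1, reference)
        c2, _ = build_catalog96(part2, reference)
        assert np.array_equal(joint.counts, np.hstack([c1.counts, c2.counts]))


class TestPairSpectrum:
    def test_categories_partition_all_records(self):
        from premasig import SimConfig, simulate_tp53_spectrum

        records, reference = simulate_tp53_spectrum(SimConfig(seed=3), 500)
        spec = build_pair_spectrum(records, reference)
        assert spec.total == 500
        assert spec.fractions().sum() == pytest.approx(1.0)

    def test_snv_and_insertion_split(self):
        reference = {"chr1": "AGAATA"}
        records = [rec(pos=2, ref="G", alt="T"),
                   rec(pos=4, ref="A", alt="AT", effect="indel-coding")]
        spec = build_pair_spectrum(records, reference)
        assert spec.to_series()["G:C>T:A"] == 1
        assert spec.to_series()["indel"] == 1
        assert spec.total == 2

    def test_cpg_category(self):
        reference = {"chr1": "ACGT"}
        spec = build_pair_spectrum([rec(pos=2, ref="C", alt="T")], reference)
        assert spec.to_series()["G:C>A:T at CpG"] == 1

    def test_missing_reference_for_cpg_split_errors(self):
        with pytest.raises(ValueError, match="reference"):
            build_pair_spectrum([rec(ref="C", alt="T")], reference=None)

    def test_spectrum_compare_identical_is_one(self):
        from premasig.mutation_catalog import PairSpectrum

        s = PairSpectrum(counts=[5, 3, 2, 1, 0, 0, 0, 4])
        assert spectrum_compare(s, s, "G:C>T:A") == 1.0

    def test_spectrum_compare_matches_fisher_oracle(self):
        from premasig.mutation_catalog import PairSpectrum

        a = PairSpectrum(counts=[0, 0, 10, 0, 0, 0, 0, 10])
        b = PairSpectrum(counts=[0, 0, 0, 0, 0, 0, 0, 20])
        p = spectrum_compare(a, b, "G:C>T:A")
        assert p == pytest.approx(enumeration_fisher_2x2([[10, 10], [0, 20]]), rel=1e-6)

    def test_zero_category_both_sides(self):
        from premasig.mutation_catalog import PairSpectrum

        a = PairSpectrum(counts=[1, 0, 0, 0, 0, 0, 0, 0])
        b = PairSpectrum(counts=[2, 0, 0, 0, 0, 0, 0, 0])
        assert spectrum_compare(a, b, "G:C>T:A") == 1.0


class TestRatesAndPanel:
    def test_rate_per_mb(self):
        records = [rec(sample="s1", pos=100 + i) for i in range(94)]
        rates, mean = mutation_rate_per_mb(records, capture_mb=47.0)
        assert rates["s1"] == pytest.approx(2.0)
        assert mean == pytest.approx(2.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mutation_rate_per_mb([], capture_mb=47.0)

    def test_panel_summary(self):
        records = [rec(sample="c1", gene="TP53"), rec(sample="c2", gene="TP53"),
                   rec(sample="c2", pos=200, gene="PIK3CA")]
        frac, per_gene = panel_summary(records, n_cases=4)
        assert frac == pytest.approx(0.5)
        assert per_gene["TP53"] == pytest.approx(0.5)
        assert per_gene["PIK3CA"] == pytest.approx(0.25)
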