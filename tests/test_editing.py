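"""Editing filter cascade, event typing, region annotation and comparison."""

import numpy as np
import pytest

from m6akit.annotation import GeneModel, IntervalMask
from m6akit.editing import (
    EditingSite,
    classify_edit_type,
    compare_editing,
    filter_cascade,
    high_confidence,
    homopolymer_check,
    annotate_region,
)
from m6akit.synthetic import SimConfig, simulate_editing


def empty_masks():
    return {
        name: IntervalMask(name)
        for name in ("snp", "alu", "simple_repeat", "splice_junction", "similarity")
    }


def site(pos=50, offsets=(10, 20, 30, 40), total=20, ref="A", alt="G", strand="+"):
    return EditingSite(
        chrom="c", pos=pos, ref_base=ref, alt_base=alt, strand=strand,
        total_reads=total, alt_read_offsets=offsets,
    )


REF = {"c": "ACGT" * 50}


class TestCascade:
    def test_snp_masked_site_fails_first(self):
        masks = empty_masks()
        masks["snp"].add("c", 50, 51)
        masks["alu"].add("c", 40, 60)  # SNP removal applies even inside Alu
        s = site()
        filter_cascade([s], masks, REF)
        assert s.filter_status == "snp"

    def test_first_six_bases_discounted(self):
        s = site(offsets=(2, 3, 4, 60))
        assert s.alt_reads == 1
        filter_cascade([s], empty_masks(), REF)
        assert s.filter_status == "support"

    def test_junction_distance_boundary(self):
        near, far = site(pos=50), site(pos=50)
        masks_near, masks_far = empty_masks(), empty_masks()
        masks_near["splice_junction"].add("c", 54, 55)  # 4 nt away -> removed
        masks_far["splice_junction"].add("c", 55, 56)  # 5 nt away -> kept
        filter_cascade([near], masks_near, REF)
        filter_cascade([far], masks_far, REF)
        assert near.filter_status == "splice_junction"
        assert far.filter_status == "pass"

    def test_alu_sites_skip_downstream_filters(self):
        masks = empty_masks()
        masks["alu"].add("c", 40, 60)
        masks["simple_repeat"].add("c", 45, 55)
        s = site(offsets=(10, 20))  # would fail support if non-Alu
        filter_cascade([s], masks, REF)
        assert s.filter_status == "pass" and s.in_alu

    def test_strict_all_applies_filters_inside_alu(self):
        masks = empty_masks()
        masks["alu"].add("c", 40, 60)
        s = site(offsets=(10, 20))
        filter_cascade([s], masks, REF, strict_all=True)
        assert s.filter_status == "support"

    def test_missing_mask_named(self):
        masks = empty_masks()
        del masks["similarity"]
        with pytest.raises(KeyError, match="similarity"):
            filter_cascade([site()], masks, REF)

    def test_order_independence(self, rng):
        cfg = SimConfig(seed=3)
        sites, masks, ref, _ = simulate_editing(cfg)
        filter_cascade(sites, masks, ref)
        statuses = {(s.chrom, s.pos): s.filter_status for s in sites}
        shuffled = list(sites)
        rng.shuffle(shuffled)
        filter_cascade(shuffled, masks, ref)
        assert all(statuses[(s.chrom, s.pos)] == s.filter_status for s in shuffled)


class TestDecoyFixture:
    def test_each_decoy_fails_its_own_filter(self):
        cfg = SimConfig(seed=3)
        sites, masks, ref, truth = simulate_editing(cfg)
        assert len(sites) == 120  # 50 true + 7 classes x 10 decoys
        filter_cascade(sites, masks, ref)
        status = {(s.chrom, s.pos): s.filter_status for s in sites}
        for row in truth.itertuples():
            assert status[(row.chrom, row.pos)] == row.expected_filter
        survivors = sum(1 for s in sites if s.filter_status == "pass")
        assert survivors == cfg.n_true_sites


class TestHomopolymer:
    def test_run_of_five_covering_site_removed(self):
        ref = {"c": "GCGT" + "AAAAA" + "CGTG"}
        s = site(pos=6, ref="A")
        assert homopolymer_check(s, ref)

    def test_run_of_four_kept(self):
        ref = {"c": "GCGT" + "AAAA" + "CGTG"}
        assert not homopolymer_check(site(pos=5, ref="A"), ref)

    def test_adjacent_run_does_not_count(self):
        # site base C sits next to a 6-run of A but outside it
        ref = {"c": "GC" + "AAAAAA" + "CTGT"}
        assert not homopolymer_check(site(pos=8, ref="C"), ref)


class TestHighConfidence:
    @pytest.mark.parametrize(
        "total,n_alt,expected",
        [(10, 2, True), (9, 5, False), (100, 19, False), (100, 20, True)],
    )
    def test_inclusive_bounds(self, total, n_alt, expected):
        s = site(total=total, offsets=tuple(range(10, 10 + n_alt)))
        assert high_confidence(s) is expected


class TestEditType:
    @pytest.mark.parametrize(
        "ref,alt,strand,expected",
        [
            ("A", "G", "+", "A_to_I"),
            ("T", "C", "-", "A_to_I"),
            ("C", "T", "+", "C_to_U"),
            ("G", "A", "-", "C_to_U"),
            ("G", "A", ".", "C_to_U"),
            ("T", "C", ".", "A_to_I"),
            ("A", "C", "+", "other"),
            ("A", "G", "-", "other"),
        ],
    )
    def test_typing(self, ref, alt, strand, expected):
        assert classify_edit_type(ref, alt, strand) == expected

    def test_strand_consistency(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                plus = classify_edit_type(ref, alt, "+")
                minus = classify_edit_type(comp[ref], comp[alt], "-")
                assert plus == minus


class TestRegionAnnotation:
    def _model(self):
        # + strand, single exon 0..30, CDS tx [6, 27)
        return {
            "G": GeneModel(
                gene_id="G", transcript_id="T", chrom="c", strand="+",
                exons=((0, 30),), cds_start_tx=6, cds_end_tx=27,
            )
        }

    def test_synonymous_substitution(self):
        # codon GGA -> GGG (Gly -> Gly) at CDS offset 0..2
        ref = {"c": "AAAAAA" + "GGATTTAAACCCGGGTTTAAA" + "TTT"}
        s = site(pos=8, ref="A", alt="G")
        annotate_region(s, self._model(), ref)
        assert s.region == "exonic" and s.codon_effect == "synonymous"

    def test_nonsynonymous_substitution(self):
        # codon AAA -> AGA (Lys -> Arg)
        ref = {"c": "AAAAAA" + "AAATTTAAACCCGGGTTTAAA" + "TTT"}
        s = site(pos=7, ref="A", alt="G")
        annotate_region(s, self._model(), ref)
        assert s.codon_effect == "nonsynonymous"

    def test_utr_and_intergenic(self):
        ref = {"c": "A" * 40}
        utr = site(pos=2)
        annotate_region(utr, self._model(), ref)
        assert utr.region == "5'UTR"
        inter = site(pos=35)
        annotate_region(inter, self._model(), ref)
        assert inter.region == "intergenic" and inter.codon_effect == "none"

    def test_intronic(self):
        models = {
            "G": GeneModel(
                gene_id="G", transcript_id="T", chrom="c", strand="+",
                exons=((0, 10), (20, 30)),
            )
        }
        s = site(pos=15)
        annotate_region(s, models, {"c": "A" * 40})
        assert s.region == "intronic"


class TestCompareEditing:
    def _passing(self, n, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            total = 20
            n_alt = int(rng.integers(5, 16))
            s = site(pos=100 + i, total=total,
                     offsets=tuple(10 + j for j in range(n_alt)))
            out.append(s)
        return out

    def test_identical_sets(self):
        a = self._passing(30)
        out = compare_editing(a, a)
        assert out["pct_change"] == 0.0
        assert out["ks_p"] == pytest.approx(1.0)

    def test_removed_fraction(self):
        a = self._passing(100)
        b = a[: 63]
        out = compare_editing(a, b)
        assert out["pct_change"] == pytest.approx(37.0)

    def test_planted_ratio_shift_detected(self):
        a = self._passing(150, seed=1)
        rng = np.random.default_rng(2)
        b = []
        for i in range(150):
            n_alt = int(rng.integers(5, 9))  # systematically lower ratios
            b.append(site(pos=500 + i, total=20,
                          offsets=tuple(10 + j for j in range(n_alt))))
        out = compare_editing(a, b)
        assert out["ks_p"] < 0.01
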