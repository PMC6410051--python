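"""Peak-set comparison, DE thresholds, target bookkeeping, CDF statistics."""

import numpy as np
import pandas as pd
import pytest

from m6akit.integrate import (
    abundance_by_group,
    apply_de_thresholds,
    cdf_compare,
    classify_rbp,
    classify_targets,
    compare_peak_sets,
    summarize_peak_classes,
    summarize_targets,
)
from m6akit.peaks import Peak


def peak(tid, start, end, score, gene=None):
    return Peak(tid, start, end, score, 0.01, (start + end) // 2, 2,
                gene_id=gene or tid)


class TestComparePeakSets:
    def test_control_only_is_lost(self):
        table, gene_class = compare_peak_sets([peak("T1", 0, 100, 3.0)], [])
        assert table["peak_class"].tolist() == ["lost"]
        assert gene_class["T1"] == "lost"

    def test_small_drop_is_common(self):
        table, _ = compare_peak_sets(
            [peak("T1", 0, 100, 3.0)], [peak("T1", 50, 150, 2.9)]
        )
        assert table["peak_class"].tolist() == ["common"]

    def test_large_drop_is_reduced(self):
        table, _ = compare_peak_sets(
            [peak("T1", 0, 100, 3.0)], [peak("T1", 50, 150, 1.5)]
        )
        assert table["peak_class"].tolist() == ["reduced"]

    def test_silenced_only_is_independent(self):
        table, gene_class = compare_peak_sets([], [peak("T1", 0, 100, 2.0)])
        assert table["peak_class"].tolist() == ["independent"]
        assert gene_class["T1"] == "independent"

    def test_swap_maps_lost_to_independent_and_keeps_common(self):
        ctrl = [peak("T1", 0, 100, 3.0), peak("T2", 0, 100, 2.0)]
        sil = [peak("T2", 20, 120, 2.1)]
        fwd, _ = compare_peak_sets(ctrl, sil)
        rev, _ = compare_peak_sets(sil, ctrl)
        fwd_by = fwd.set_index(["transcript_id", "condition"])["peak_class"]
        rev_by = rev.set_index(["transcript_id", "condition"])["peak_class"]
        assert fwd_by[("T1", "control")] == "lost"
        assert rev_by[("T1", "silenced")] == "independent"
        assert fwd_by[("T2", "control")] == "common"
        assert rev_by[("T2", "control")] == "common"

    def test_gene_priority_lost_over_common(self):
        ctrl = [peak("T1", 0, 100, 3.0, gene="G"), peak("T1", 300, 400, 3.0, gene="G")]
        sil = [peak("T1", 0, 100, 3.0, gene="G")]
        _, gene_class = compare_peak_sets(ctrl, sil)
        assert gene_class["G"] == "lost"


class TestDEThresholds:
    @pytest.mark.parametrize(
        "lfc,padj,regulated,direction",
        [
            (-1.0, 0.001, True, "down"),
            (-0.5, 0.001, False, "none"),
            (-2.0, 0.05, False, "none"),  # strict p cutoff
            (1.0, 0.01, True, "up"),
            (np.log2(1.5), 0.01, False, "none"),  # strict FC cutoff
        ],
    )
    def test_strict_cutoffs(self, lfc, padj, regulated, direction):
        de = pd.DataFrame(
            {"gene_id": ["g"], "log2_fold_change": [lfc], "p_adjusted": [padj]}
        )
        out = apply_de_thresholds(de)
        assert bool(out["regulated"][0]) is regulated
        assert out["direction"][0] == direction


def study_scale_records():
    """Target-record universe at the published component counts of the study.

    1701 direct genes (1680 lost + 21 reduced): 1461 regulated down, 6 up,
    234 unregulated; 15272 indirect regulated (8011 up / 7261 down) of which
    9830 protein-coding (3702 up / 6128 down); remainder unaffected.
    """
    rows = []

    def add(n, peak_class, regulated, direction, biotype="protein_coding"):
        rows.extend(
            {
                "peak_class": peak_class,
                "regulated": regulated,
                "direction": direction,
                "biotype": biotype,
                "target_class": (
                    ("direct_regulated" if regulated else "direct_unregulated")
                    if peak_class in ("lost", "reduced")
                    else ("indirect_regulated" if regulated else "unaffected")
                ),
            }
            for _ in range(n)
        )

    add(1461 - 21, "lost", True, "down")
    add(21, "reduced", True, "down")
    add(6, "lost", True, "up")
    add(234, "lost", False, "none")
    add(3702, "none", True, "up", biotype="protein_coding")
    add(8011 - 3702, "none", True, "up", biotype="lincRNA")
    add(6128, "none", True, "down", biotype="protein_coding")
    add(7261 - 6128, "none", True, "down", biotype="lincRNA")
    add(500, "none", False, "none")
    df = pd.DataFrame(rows)
    df["gene_id"] = [f"g{i}" for i in range(len(df))]
    return df


class TestTargetBookkeeping:
    def test_classes_partition_gene_universe(self):
        gene_class = {"A": "lost", "B": "common", "D": "independent"}
        de = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C", "D", "E"],
                "log2_fold_change": [-2.0, 1.0, -1.5, 0.1, 0.0],
                "p_adjusted": [0.001, 0.002, 0.01, 0.9, 0.5],
            }
        )
        records = classify_targets(gene_class, de)
        assert len(records) == 5
        assert records.set_index("gene_id")["target_class"].to_dict() == {
            "A": "direct_regulated",
            "B": "indirect_regulated",
            "C": "indirect_regulated",
            "D": "unaffected",
            "E": "unaffected",
        }
        summary = summarize_targets(records)
        assert (
            summary["n_direct"]
            + summary["n_indirect_regulated"]
            + summary["n_unaffected"]
            == len(records)
        )

    def test_printed_percentages_reproduced(self):
        s = summarize_targets(study_scale_records())
        assert round(s["pct_direct_regulated"], 2) == 86.24
        assert round(s["pct_direct_regulated_down"], 1) == 99.6
        assert round(s["pct_direct_unregulated"], 1) == 13.8
        assert round(s["pct_indirect_of_regulated"], 2) == 91.24
        assert round(s["pct_indirect_up"], 2) == 52.46
        assert round(s["pct_indirect_down"], 1) == 47.5
        assert round(s["pct_indirect_pc_down"], 2) == 62.34
        assert round(s["pct_indirect_pc_up"], 1) == 37.7

    def test_all_unaffected_guards_zero_division(self):
        records = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "peak_class": ["none", "none"],
                "regulated": [False, False],
                "direction": ["none", "none"],
                "biotype": ["protein_coding"] * 2,
                "target_class": ["unaffected", "unaffected"],
            }
        )
        s = summarize_targets(records)
        assert s["pct_direct_regulated"] is None
        assert s["pct_indirect_up"] is None

    def test_peak_total_consistency(self):
        ctrl = [peak("T1", 0, 100, 3.0), peak("T2", 0, 100, 3.0),
                peak("T3", 0, 100, 3.0)]
        sil = [peak("T2", 50, 150, 2.9), peak("T4", 0, 100, 2.0)]
        table, _ = compare_peak_sets(ctrl, sil)
        s = summarize_peak_classes(table)
        assert s["total_consistent"]
        assert s["n_lost_peaks"] + s["n_overlapping_peaks"] == s["n_control_peaks"]


class TestCdfCompare:
    def test_identical_samples(self):
        d, p, shift = cdf_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0 and p == pytest.approx(1.0) and shift == 0.0

    def test_disjoint_supports(self):
        d, _, _ = cdf_compare([0, 0, 0, 0], [1, 1, 1, 1])
        assert d == 1.0

    def test_shifted_normals_significant(self):
        rng = np.random.default_rng(11)
        a = rng.normal(1, 1, 500)
        b = rng.normal(0, 1, 500)
        _, p, shift = cdf_compare(a, b)
        assert p < 1e-6
        assert shift > 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cdf_compare([], [1.0])


class TestRbpClassification:
    def test_planted_shifts(self):
        rng = np.random.default_rng(7)
        without = rng.normal(0, 1, 200)
        assert classify_rbp(rng.normal(-1, 1, 200), without) == "stabilizer"
        assert classify_rbp(rng.normal(+1, 1, 200), without) == "destabilizer"

    def test_identical_distributions_neutral(self):
        vals = np.linspace(-1, 1, 100)
        assert classify_rbp(vals, vals) == "neutral"


class TestAbundance:
    def test_planted_high_m6a_group(self, rng):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(400)],
                "abundance": np.concatenate(
                    [rng.lognormal(2, 1, 200), rng.lognormal(0, 1, 200)]
                ),
                "m6a": [True] * 200 + [False] * 200,
                "biotype": ["protein_coding"] * 400,
            }
        )
        out = abundance_by_group(df, biotypes=("protein_coding",))
        ks = out["protein_coding"]["ks"]
        assert ks["p"] < 1e-6 and ks["median_shift"] > 0

    def test_single_group_has_cdf_only(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "abundance": [1.0, 2.0],
                "m6a": [True, True],
                "biotype": ["lincRNA"] * 2,
            }
        )
        out = abundance_by_group(df, biotypes=("lincRNA",))
        assert "ks" not in out["lincRNA"]
        assert "m6a" in out["lincRNA"]["cdf"]

    def test_empty_biotype_rejected(self):
        df = pd.DataFrame(
            {"gene_id": ["a"], "abundance": [1.0], "m6a": [True],
             "biotype": ["protein_coding"]}
        )
        with pytest.raises(ValueError):
            abundance_by_group(df, biotypes=("lincRNA",))
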