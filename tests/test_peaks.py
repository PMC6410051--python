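"""Window construction, WinScore, exact tests, BH and peak assembly."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6akit.peaks import (
    Peak,
    WindowStats,
    bh_adjust,
    call_peaks,
    fisher_window_test,
    make_windows,
    merge_windows,
    summit_flanks,
    win_score,
)
from m6akit.tracks import normalize_track


def hypergeom_tail(read_ip, gene_ip, read_ctrl, gene_ctrl) -> float:
    """Exact one-sided tail sum over 2x2 tables with fixed margins."""
    N = gene_ip + gene_ctrl
    K = gene_ip
    n = read_ip + read_ctrl
    total = Fraction(math.comb(N, n))
    p = Fraction(0)
    for k in range(read_ip, min(K, n) + 1):
        if n - k > N - K:
            continue
        p += Fraction(math.comb(K, k) * math.comb(N - K, n - k))
    return float(p / total)


def bh_reference(p):
    """Quadratic-time BH from the definition: padj_i = min_{p_j >= p_i} p_j*n/rank_j."""
    p = list(p)
    n = len(p)
    sp = sorted(p)
    result = []
    for pi in p:
        vals = [pj * n / (j + 1) for j, pj in enumerate(sp) if pj >= pi]
        result.append(min(min(vals), 1.0))
    return result


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (100, [(0, 100)]),
            (150, [(0, 100), (50, 150)]),
            (249, [(0, 100), (50, 150), (100, 200), (150, 249)]),
            (40, []),
        ],
    )
    def test_enumeration(self, length, expected):
        assert make_windows(length) == expected

    @settings(max_examples=100, deadline=None)
    @given(length=st.integers(51, 5000))
    def test_windows_tile_and_extend(self, length):
        ws = make_windows(length)
        assert ws[0][0] == 0
        for (s1, e1), (s2, e2) in zip(ws, ws[1:]):
            assert s2 == s1 + 50
            assert e2 > e1  # every window adds new positions
        assert all(e - s > 50 for s, e in ws)
        assert ws[-1][1] == length  # coverage reaches the transcript end


class TestWinScore:
    @pytest.mark.parametrize(
        "args,expected",
        [((10, 10, 10, 10), 0.0), ((40, 10, 20, 10), 1.0), ((5, 10, 20, 10), -2.0)],
    )
    def test_closed_form(self, args, expected):
        assert win_score(*args) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        vals=st.tuples(
            *[st.floats(0.1, 1e4, allow_nan=False) for _ in range(4)]
        )
    )
    def test_ip_control_antisymmetry(self, vals):
        a, b, c, d = vals
        assert win_score(a, b, c, d) == pytest.approx(-win_score(c, d, a, b), rel=1e-9)


class TestFisher:
    def test_degenerate_margin(self):
        assert fisher_window_test(0, 10, 0, 10) == pytest.approx(1.0)

    def test_small_table_exact(self):
        # single consistent extreme table: C(3,3)C(3,0)/C(6,3) = 1/20
        assert fisher_window_test(3, 3, 0, 3) == pytest.approx(0.05, abs=1e-12)

    def test_balanced_table_matches_oracle(self):
        expected = hypergeom_tail(10, 100, 10, 100)
        assert fisher_window_test(10, 100, 10, 100) == pytest.approx(expected, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_window_test(5, 3, 0, 10)

    def test_exhaustive_small_margins(self):
        for gene_ip in range(1, 13):
            for gene_ctrl in range(1, 13):
                for read_ip in range(0, gene_ip + 1):
                    for read_ctrl in range(0, gene_ctrl + 1):
                        expected = hypergeom_tail(read_ip, gene_ip, read_ctrl, gene_ctrl)
                        got = fisher_window_test(read_ip, gene_ip, read_ctrl, gene_ctrl)
                        assert got == pytest.approx(expected, abs=1e-12)

    def test_sampled_margins_to_60(self, rng):
        for _ in range(400):
            gene_ip = int(rng.integers(1, 61))
            gene_ctrl = int(rng.integers(1, 61))
            read_ip = int(rng.integers(0, gene_ip + 1))
            read_ctrl = int(rng.integers(0, gene_ctrl + 1))
            expected = hypergeom_tail(read_ip, gene_ip, read_ctrl, gene_ctrl)
            got = fisher_window_test(read_ip, gene_ip, read_ctrl, gene_ctrl)
            assert got == pytest.approx(expected, abs=1e-12)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_computed_vector(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_quadratic_reference(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_reference(p.tolist()), atol=1e-12)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=200)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_output_dominates_input(self, p):
        out = bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0)


class TestPeakAssembly:
    def _window(self, start, end, score=2.0, padj=0.01):
        return WindowStats(
            transcript_id="T", start=start, end=end, mean_win_ip=0, mean_win_ctrl=0,
            median_gene_ip=1, median_gene_ctrl=1, win_score=score, read_ip=0,
            read_ctrl=0, gene_ip=0, gene_ctrl=0, p_value=padj, p_adjusted=padj,
        )

    def test_overlapping_windows_merge(self):
        runs = merge_windows([self._window(100, 200), self._window(150, 250)])
        assert len(runs) == 1
        assert (runs[0][0].start, max(w.end for w in runs[0])) == (100, 250)

    def test_disjoint_windows_stay_separate(self):
        runs = merge_windows([self._window(0, 100), self._window(300, 400)])
        assert len(runs) == 2

    def test_normalize_track_scaling(self):
        assert normalize_track(np.array([5.0]), 2_000_000)[0] == pytest.approx(2.5)
        vals = np.array([0.0, 3.0, 1.0])
        norm = normalize_track(vals, 123456)
        assert norm[0] == 0.0
        assert int(np.argmax(norm)) == int(np.argmax(vals))

    def test_normalize_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            normalize_track(np.array([1.0]), 0)


class TestSummitFlanks:
    def _peak(self, summit):
        return Peak("T", 0, 100, 2.0, 0.01, summit, 1)

    def test_interior_summit(self):
        seq = "A" * 500
        assert len(summit_flanks(self._peak(60), seq)) == 101
        # window is [10, 111)
        seq2 = "".join(chr(65 + (i % 26)) for i in range(500))
        assert summit_flanks(self._peak(60), seq2) == seq2[10:111]

    def test_clipped_at_start(self):
        seq = "ACGT" * 100
        assert summit_flanks(self._peak(10), seq) == seq[0:61]

    def test_never_longer_than_101(self):
        seq = "ACGT" * 10
        for summit in range(len(seq)):
            assert len(summit_flanks(self._peak(summit), seq)) <= 101
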