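"""Window-scan m6A peak calling from matched IP and input coverage tracks.

The caller scans 100-nt windows advancing by 50 nt along each transcript and
scores every window with the log2 enrichment statistic

    WinScore = log2((MeanWinIP / MedianGeneIP) / (MeanWinControl / MedianGeneControl))

i.e. the window mean of each library is first normalized by that library's
gene-median coverage, so transcript abundance cancels and only local IP
enrichment remains.  Windows at or above the enrichment cutoff (default 1.0,
two-fold) are tested with a one-sided Fisher exact test of window read counts
against the rest of the gene, p-values are Benjamini-Hochberg corrected in one
batch across all tested windows transcriptome-wide, and surviving windows
(p_adjusted < alpha) that overlap or touch are merged into peaks.

Fisher's test needs integer counts while the inputs are per-nt coverage, so
read units are derived as round(coverage_sum / read_length) with one
pseudo-read added to window and gene totals of both libraries (avoids empty
cells; read_length defaults to 50 nt, single-end).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneModel
from .tracks import CoverageTrack, normalize_track

log = logging.getLogger(__name__)

__all__ = [
    "WindowStats",
    "Peak",
    "make_windows",
    "win_score",
    "fisher_window_test",
    "bh_adjust",
    "call_peaks",
    "summit_flanks",
]

WINDOW_SIZE = 100
WINDOW_STEP = 50


@dataclass
class WindowStats:
    transcript_id: str
    start: int
    end: int
    mean_win_ip: float
    mean_win_ctrl: float
    median_gene_ip: float
    median_gene_ctrl: float
    win_score: float
    read_ip: int
    read_ctrl: int
    gene_ip: int
    gene_ctrl: int
    p_value: float = float("nan")
    p_adjusted: float = float("nan")


@dataclass
class Peak:
    transcript_id: str
    start: int
    end: int
    enrichment_score: float
    p_adjusted: float
    summit: int
    n_windows: int
    region_class: str = "none"
    gene_id: str = ""

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def make_windows(
    transcript_length: int, size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> list[tuple[int, int]]:
    """Sliding windows [s, min(s+size, L)) at starts 0, step, 2*step, ...

    A trailing window is kept only if it extends past the previous window's
    end (width > step); a shorter tail adds no new positions beyond the
    overlap and is dropped.  Transcripts shorter than ``step`` yield no
    windows.
    """
    if transcript_length <= step:
        log.debug("transcript of length %d too short to window", transcript_length)
        return []
    return [
        (s, min(s + size, transcript_length))
        for s in range(0, transcript_length - step, step)
    ]


def win_score(
    mean_win_ip: float,
    median_gene_ip: float,
    mean_win_ctrl: float,
    median_gene_ctrl: float,
) -> float:
    """log2 window enrichment of IP over control, gene-median normalized."""
    if min(median_gene_ip, median_gene_ctrl, mean_win_ctrl) <= 0:
        raise ValueError("win_score requires positive control mean and medians")
    return math.log2(
        (mean_win_ip / median_gene_ip) / (mean_win_ctrl / median_gene_ctrl)
    )


def fisher_window_test(
    read_ip: int, gene_ip: int, read_ctrl: int, gene_ctrl: int
) -> float:
    """One-sided (IP-enrichment) Fisher exact p for window vs rest-of-gene.

    The 2x2 table is [[read_ip, gene_ip - read_ip], [read_ctrl,
    gene_ctrl - read_ctrl]]; the one-sided p equals the hypergeometric tail
    sum P(X >= read_ip) at fixed margins.
    """
    cells = (
        read_ip,
        gene_ip - read_ip,
        read_ctrl,
        gene_ctrl - read_ctrl,
    )
    if any(c < 0 for c in cells):
        raise ValueError(f"negative cell in Fisher table: {cells}")
    _, p = stats.fisher_exact(
        [[cells[0], cells[1]], [cells[2], cells[3]]], alternative="greater"
    )
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _read_units(cov_sum: float, read_length: int) -> int:
    return int(round(cov_sum / read_length))


def scan_windows(
    ip_tracks: Mapping[str, CoverageTrack],
    ctrl_tracks: Mapping[str, CoverageTrack],
    enrichment_cutoff: float = 1.0,
    read_length: int = 50,
) -> list[WindowStats]:
    """Score every window of every shared transcript; mark tested windows.

    Returns WindowStats for windows at/above the enrichment cutoff, with
    Fisher p-values filled in (BH correction is applied by the caller over
    the full batch).
    """
    tested: list[WindowStats] = []
    for tid in sorted(ip_tracks):
        if tid not in ctrl_tracks:
            log.warning("transcript %s absent from control library; skipped", tid)
            continue
        cov_ip = ip_tracks[tid].values
        cov_ctrl = ctrl_tracks[tid].values
        if cov_ip.size != cov_ctrl.size:
            log.warning("transcript %s has mismatched track lengths; skipped", tid)
            continue
        med_ip = float(np.median(cov_ip))
        med_ctrl = float(np.median(cov_ctrl))
        if med_ip <= 0 or med_ctrl <= 0:
            log.warning(
                "transcript %s has zero median coverage; excluded from calling", tid
            )
            continue
        gene_ip = _read_units(float(cov_ip.sum()), read_length) + 1
        gene_ctrl = _read_units(float(cov_ctrl.sum()), read_length) + 1
        for s, e in make_windows(cov_ip.size):
            width = e - s
            sum_ip = float(cov_ip[s:e].sum())
            sum_ctrl = float(cov_ctrl[s:e].sum())
            # one pseudo-read on the window totals of both libraries
            mean_ip = (sum_ip + read_length) / width
            mean_ctrl = (sum_ctrl + read_length) / width
            ws = win_score(mean_ip, med_ip, mean_ctrl, med_ctrl)
            if ws < enrichment_cutoff:
                continue
            read_ip = min(_read_units(sum_ip, read_length) + 1, gene_ip)
            read_ctrl = min(_read_units(sum_ctrl, read_length) + 1, gene_ctrl)
            w = WindowStats(
                transcript_id=tid,
                start=s,
                end=e,
                mean_win_ip=mean_ip,
                mean_win_ctrl=mean_ctrl,
                median_gene_ip=med_ip,
                median_gene_ctrl=med_ctrl,
                win_score=ws,
                read_ip=read_ip,
                read_ctrl=read_ctrl,
                gene_ip=gene_ip,
                gene_ctrl=gene_ctrl,
            )
            w.p_value = fisher_window_test(read_ip, gene_ip, read_ctrl, gene_ctrl)
            tested.append(w)
    return tested


def _classify_region(model: GeneModel | None, tpos: int) -> str:
    if model is None:
        return "none"
    if not model.is_coding:
        return "noncoding"
    if tpos < model.cds_start_tx:
        return "5'UTR"
    if tpos < model.cds_end_tx:
        return "CDS"
    return "3'UTR"


def merge_windows(windows: Sequence[WindowStats]) -> list[list[WindowStats]]:
    """Group overlapping or adjacent windows of one transcript into runs."""
    runs: list[list[WindowStats]] = []
    for w in sorted(windows, key=lambda w: w.start):
        if runs and w.start <= runs[-1][-1].end:
            runs[-1].append(w)
        else:
            runs.append([w])
    return runs


def call_peaks(
    ip_tracks: Mapping[str, CoverageTrack],
    ctrl_tracks: Mapping[str, CoverageTrack],
    models: Mapping[str, GeneModel] | None = None,
    enrichment_cutoff: float = 1.0,
    alpha: float = 0.05,
    read_length: int = 50,
) -> tuple[list[Peak], list[WindowStats]]:
    """Full pipeline: windows -> WinScore -> Fisher -> BH -> merge -> peaks.

    ``models`` (keyed by transcript_id) is optional and only used to attach
    gene ids and 5'UTR/CDS/3'UTR region classes to the peaks.
    """
    tested = scan_windows(
        ip_tracks, ctrl_tracks, enrichment_cutoff=enrichment_cutoff,
        read_length=read_length,
    )
    if tested:
        padj = bh_adjust([w.p_value for w in tested])
        for w, pa in zip(tested, padj):
            w.p_adjusted = float(pa)
    by_tid: dict[str, list[WindowStats]] = {}
    for w in tested:
        if w.p_adjusted < alpha:
            by_tid.setdefault(w.transcript_id, []).append(w)

    tx_models = {}
    if models:
        tx_models = {m.transcript_id: m for m in models.values()}

    peaks: list[Peak] = []
    for tid in sorted(by_tid):
        cov_ip = ip_tracks[tid].values
        norm = normalize_track(cov_ip, ip_tracks[tid].library_size)
        model = tx_models.get(tid)
        for run in merge_windows(by_tid[tid]):
            start = run[0].start
            end = max(w.end for w in run)
            local = norm[start:end]
            summit = start + int(np.argmax(local))  # leftmost on ties
            mid = (start + end) // 2
            peaks.append(
                Peak(
                    transcript_id=tid,
                    start=start,
                    end=end,
                    enrichment_score=max(w.win_score for w in run),
                    p_adjusted=min(w.p_adjusted for w in run),
                    summit=summit,
                    n_windows=len(run),
                    region_class=_classify_region(model, mid),
                    gene_id=model.gene_id if model else "",
                )
            )
    return peaks, tested


def summit_flanks(peak: Peak, transcript_sequence: str, flank: int = 50) -> str:
    """Sequence of summit +/- ``flank`` nt (<= 2*flank+1), clipped at ends.

    Used to emit FASTA records around peak summits for external motif tools.
    """
    lo = max(0, peak.summit - flank)
    hi = min(len(transcript_sequence), peak.summit + flank + 1)
    return transcript_sequence[lo:hi]


def peaks_to_dataframe(peaks: Sequence[Peak]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "transcript_id": p.transcript_id,
                "gene_id": p.gene_id,
                "start": p.start,
                "end": p.end,
                "enrichment_score": p.enrichment_score,
                "p_adjusted": p.p_adjusted,
                "summit": p.summit,
                "n_windows": p.n_windows,
                "region_class": p.region_class,
            }
            for p in peaks
        ],
        columns=[
            "transcript_id",
            "gene_id",
            "start",
            "end",
            "enrichment_score",
            "p_adjusted",
            "summit",
            "n_windows",
            "region_class",
        ],
    )


def write_peaks_bed(
    peaks: Sequence[Peak],
    models: Mapping[str, GeneModel],
    path,
) -> None:
    """Genome-projected BED6 output (one row per contiguous genomic block)."""
    tx_models = {m.transcript_id: m for m in models.values()}
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            model = tx_models.get(p.transcript_id)
            if model is None:
                continue
            for a, b in model.transcript_interval_to_genome(p.start, p.end):
                score = min(int(round(p.enrichment_score * 100)), 1000)
                fh.write(
                    f"{model.chrom}\t{a}\t{b}\tpeak_{i}\t{score}\t{model.strand}\n"
                )
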