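"""Post-processing of rMATS-format differential-splicing tables.

Events (SE/RI/A5SS/A3SS/MXE) are filtered by FDR < 0.05, |inclusion-level
difference| >= 0.05 (five percentage points of PSI) and inclusion+skipping
junction counts >= 10 in both conditions (summed over replicates).  Per-type
inclusion levels are compared between conditions with the Wilcoxon rank-sum
test, and exon-skipping events are tested for m6A dependence by comparing
inclusion differences between m6A-modified and unmodified genes (KS) and by
flagging skipped exons overlapping control-condition peaks.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GeneModel
from .peaks import Peak

log = logging.getLogger(__name__)

__all__ = [
    "read_rmats",
    "filter_events",
    "compare_inclusion_by_type",
    "m6a_dependence_of_SE",
]

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")


def _rep_sum(col: pd.Series) -> np.ndarray:
    """Sum of comma-separated per-replicate counts."""
    return col.astype(str).map(
        lambda s: sum(int(float(x)) for x in s.split(",") if x not in ("", "NA"))
    ).to_numpy()


def _rep_mean(col: pd.Series) -> np.ndarray:
    """Mean of comma-separated per-replicate PSI values (NA dropped)."""
    def mean(s: str) -> float:
        vals = [float(x) for x in str(s).split(",") if x not in ("", "NA")]
        return float(np.mean(vals)) if vals else float("nan")

    return col.map(mean).to_numpy()


def read_rmats(path) -> pd.DataFrame:
    """Read an rMATS JC-dialect table (tab-separated)."""
    df = pd.read_csv(path, sep="\t")
    required = {
        "event_type", "GeneID", "IJC_SAMPLE_1", "SJC_SAMPLE_1",
        "IJC_SAMPLE_2", "SJC_SAMPLE_2", "IncLevel1", "IncLevel2",
        "IncLevelDifference", "FDR",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rMATS table missing columns: {sorted(missing)}")
    return df


def filter_events(
    events: pd.DataFrame,
    fdr: float = 0.05,
    min_dpsi: float = 0.05,
    min_counts: int = 10,
) -> pd.DataFrame:
    """Retain significant, well-supported events (idempotent)."""
    ijc1 = _rep_sum(events["IJC_SAMPLE_1"])
    sjc1 = _rep_sum(events["SJC_SAMPLE_1"])
    ijc2 = _rep_sum(events["IJC_SAMPLE_2"])
    sjc2 = _rep_sum(events["SJC_SAMPLE_2"])
    keep = (
        (events["FDR"].to_numpy(dtype=float) < fdr)
        & (np.abs(events["IncLevelDifference"].to_numpy(dtype=float)) >= min_dpsi)
        & (ijc1 >= min_counts)
        & (sjc1 >= min_counts)
        & (ijc2 >= min_counts)
        & (sjc2 >= min_counts)
    )
    return events.loc[keep].reset_index(drop=True)


def compare_inclusion_by_type(events: pd.DataFrame) -> dict:
    """Per-type Wilcoxon rank-sum of inclusion levels between conditions.

    Inclusion levels are replicate means of IncLevel1 (condition 1) vs
    IncLevel2 (condition 2).  Types with fewer than 3 events per group are
    reported as None with a warning.
    """
    out: dict = {}
    for etype, sub in events.groupby("event_type"):
        psi1 = _rep_mean(sub["IncLevel1"])
        psi2 = _rep_mean(sub["IncLevel2"])
        psi1 = psi1[~np.isnan(psi1)]
        psi2 = psi2[~np.isnan(psi2)]
        if min(psi1.size, psi2.size) < 3:
            log.warning("event type %s has <3 events per group; no test", etype)
            out[etype] = {"statistic": None, "p": None,
                          "n": int(min(psi1.size, psi2.size))}
            continue
        res = stats.ranksums(psi1, psi2)
        out[etype] = {
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "n": int(sub.shape[0]),
            "median_psi_1": float(np.median(psi1)),
            "median_psi_2": float(np.median(psi2)),
        }
    return out


def _genomic_peak_trees(
    peaks: Sequence[Peak], models: Mapping[str, GeneModel]
) -> dict[str, IntervalTree]:
    tx_models = {m.transcript_id: m for m in models.values()}
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        model = tx_models.get(p.transcript_id)
        if model is None:
            continue
        for a, b in model.transcript_interval_to_genome(p.start, p.end):
            trees.setdefault(model.chrom, IntervalTree()).addi(a, b)
    return trees


def m6a_dependence_of_SE(
    events: pd.DataFrame,
    peaks: Sequence[Peak],
    models: Mapping[str, GeneModel],
) -> tuple[pd.DataFrame, dict | None]:
    """m6A dependence of exon skipping.

    Flags each SE event whose alternative exon (chr, exonStart_0base,
    exonEnd) overlaps a control-condition peak, and compares the inclusion
    differences of events on m6A-modified genes vs unmodified genes by KS.
    Returns (annotated SE table, KS summary or None when a group is empty).
    """
    se = events[events["event_type"] == "SE"].copy()
    trees = _genomic_peak_trees(peaks, models)
    m6a_genes = {p.gene_id for p in peaks if p.gene_id}

    def overlaps(row) -> bool:
        tree = trees.get(str(row.get("chr", "")))
        if tree is None:
            return False
        return bool(tree.overlap(int(row["exonStart_0base"]), int(row["exonEnd"])))

    if {"chr", "exonStart_0base", "exonEnd"} <= set(se.columns):
        se["peak_overlap"] = se.apply(overlaps, axis=1)
    else:
        se["peak_overlap"] = False
    se["m6a_gene"] = se["GeneID"].isin(m6a_genes)

    dpsi = se["IncLevelDifference"].to_numpy(dtype=float)
    with_m6a = dpsi[se["m6a_gene"].to_numpy()]
    without = dpsi[~se["m6a_gene"].to_numpy()]
    if with_m6a.size == 0 or without.size == 0:
        log.warning("SE comparison skipped: empty m6A or non-m6A group")
        return se, None
    res = stats.ks_2samp(with_m6a, without, method="asymp")
    return se, {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "median_dpsi_m6a": float(np.median(with_m6a)),
        "median_dpsi_non_m6a": float(np.median(without)),
        "n_m6a": int(with_m6a.size),
        "n_non_m6a": int(without.size),
        "frac_SE_overlap_peak": float(se["peak_overlap"].mean()) if len(se) else None,
    }
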