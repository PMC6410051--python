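"""Peak-set comparison, DE thresholding and direct/indirect target calling.

Two peak sets (control = shNT, methyltransferase-silenced = shMETTL3) are
compared peak-by-peak on shared transcript coordinates:

* lost        - control peak with no overlapping silenced peak
* reduced     - overlapping peaks, silenced enrichment lower by >= threshold
* common      - overlapping peaks within the threshold
* independent - silenced-only peak, or overlap with silenced score higher
                by >= threshold (enzyme-independent methylation)

A gene's class is the strongest among its peaks (lost > reduced > common >
independent).  Genes with lost/reduced peaks are direct targets of the
silenced methyltransferase; genes regulated at the RNA level without such
peaks are indirect targets.  DE regulation uses strict cutoffs
p_adjusted < 0.05 and |fold change| > 1.5.

Distribution comparisons (transcript abundance, fold change, RBP site
cooperation) use the two-sample Kolmogorov-Smirnov test with asymptotic
p-values; Wilcoxon rank-sum is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import Peak

log = logging.getLogger(__name__)

__all__ = [
    "DERecord",
    "TargetRecord",
    "compare_peak_sets",
    "apply_de_thresholds",
    "classify_targets",
    "summarize_targets",
    "summarize_peak_classes",
    "cdf_compare",
    "classify_rbp",
    "abundance_by_group",
]

GENE_CLASS_PRIORITY = ["lost", "reduced", "common", "independent"]


@dataclass
class DERecord:
    gene_id: str
    log2_fold_change: float
    p_adjusted: float
    biotype: str = "protein_coding"
    abundance_control: float = float("nan")
    abundance_silenced: float = float("nan")


@dataclass
class TargetRecord:
    gene_id: str
    peak_class: str  # lost/reduced/common/independent/none
    regulated: bool
    direction: str  # up/down/none
    target_class: str  # direct_regulated/direct_unregulated/indirect_regulated/unaffected


def _overlaps(a: Peak, b: Peak, min_overlap: int) -> bool:
    return (
        a.transcript_id == b.transcript_id
        and min(a.end, b.end) - max(a.start, b.start) >= min_overlap
    )


def compare_peak_sets(
    peaks_control: Sequence[Peak],
    peaks_silenced: Sequence[Peak],
    reduction_threshold: float = 1.0,
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Classify peaks between conditions and derive per-gene peak classes.

    Returns (peak table, gene_id -> class).  The peak table carries one row
    per control peak plus one per silenced-only peak, with columns
    condition/transcript_id/gene_id/start/end/score and peak_class.
    """
    by_tid: dict[str, list[Peak]] = {}
    for p in peaks_silenced:
        by_tid.setdefault(p.transcript_id, []).append(p)

    rows = []
    matched_silenced: set[int] = set()
    for p in peaks_control:
        partners = [
            q for q in by_tid.get(p.transcript_id, ())
            if _overlaps(p, q, min_overlap)
        ]
        if not partners:
            cls = "lost"
        else:
            matched_silenced.update(id(q) for q in partners)
            best = max(q.enrichment_score for q in partners)
            drop = p.enrichment_score - best
            if drop >= reduction_threshold:
                cls = "reduced"
            elif drop <= -reduction_threshold:
                cls = "independent"
            else:
                cls = "common"
        rows.append(
            {
                "condition": "control",
                "transcript_id": p.transcript_id,
                "gene_id": p.gene_id or p.transcript_id,
                "start": p.start,
                "end": p.end,
                "score": p.enrichment_score,
                "peak_class": cls,
            }
        )
    for q in peaks_silenced:
        if id(q) in matched_silenced:
            continue
        rows.append(
            {
                "condition": "silenced",
                "transcript_id": q.transcript_id,
                "gene_id": q.gene_id or q.transcript_id,
                "start": q.start,
                "end": q.end,
                "score": q.enrichment_score,
                "peak_class": "independent",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "condition", "transcript_id", "gene_id", "start", "end",
            "score", "peak_class",
        ],
    )
    gene_class: dict[str, str] = {}
    for _, row in table.iterrows():
        gid, cls = row["gene_id"], row["peak_class"]
        cur = gene_class.get(gid)
        if cur is None or GENE_CLASS_PRIORITY.index(cls) < GENE_CLASS_PRIORITY.index(cur):
            gene_class[gid] = cls
    return table, gene_class


def apply_de_thresholds(
    de_table: pd.DataFrame, alpha: float = 0.05, fold_change: float = 1.5
) -> pd.DataFrame:
    """Flag regulated genes: p_adjusted < alpha and |FC| > fold_change (strict).

    Expects columns gene_id, log2_fold_change, p_adjusted; returns a copy
    with ``regulated`` and ``direction`` columns added.
    """
    out = de_table.copy()
    lfc_cut = math.log2(fold_change)
    lfc = out["log2_fold_change"].to_numpy(dtype=float)
    padj = out["p_adjusted"].to_numpy(dtype=float)
    out["regulated"] = (padj < alpha) & (np.abs(lfc) > lfc_cut)
    out["direction"] = np.where(
        ~out["regulated"], "none", np.where(lfc > 0, "up", "down")
    )
    return out


def classify_targets(
    gene_peak_class: Mapping[str, str], de_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene target classification from peak classes and DE flags.

    direct = lost/reduced peak gene; split into regulated/unregulated by the
    DE flag.  indirect_regulated = regulated without a lost/reduced peak.
    The four classes partition the gene universe (union of DE table and
    peak-bearing genes).
    """
    de = apply_de_thresholds(de_table) if "regulated" not in de_table else de_table
    de = de.set_index("gene_id")
    genes = sorted(set(de.index) | set(gene_peak_class))
    rows = []
    for gid in genes:
        peak_class = gene_peak_class.get(gid, "none")
        regulated = bool(de["regulated"].get(gid, False))
        direction = str(de["direction"].get(gid, "none"))
        biotype = str(de["biotype"].get(gid, "unknown")) if "biotype" in de else "unknown"
        if peak_class in {"lost", "reduced"}:
            target = "direct_regulated" if regulated else "direct_unregulated"
        elif regulated:
            target = "indirect_regulated"
        else:
            target = "unaffected"
        rows.append(
            {
                "gene_id": gid,
                "peak_class": peak_class,
                "regulated": regulated,
                "direction": direction,
                "biotype": biotype,
                "target_class": target,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "peak_class", "regulated", "direction", "biotype",
                 "target_class"],
    )


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def summarize_targets(records: pd.DataFrame) -> dict:
    """Bookkeeping counts and percentages over a target-record table.

    Percentages are returned unrounded; zero denominators yield None.
    """
    t = records
    direct = t[t["target_class"].isin(["direct_regulated", "direct_unregulated"])]
    direct_reg = t[t["target_class"] == "direct_regulated"]
    direct_unreg = t[t["target_class"] == "direct_unregulated"]
    indirect = t[t["target_class"] == "indirect_regulated"]
    regulated = t[t["regulated"]]
    ind_up = indirect[indirect["direction"] == "up"]
    ind_down = indirect[indirect["direction"] == "down"]
    ind_pc = indirect[indirect["biotype"] == "protein_coding"]
    ind_pc_up = ind_pc[ind_pc["direction"] == "up"]
    ind_pc_down = ind_pc[ind_pc["direction"] == "down"]
    dr_down = direct_reg[direct_reg["direction"] == "down"]

    return {
        "n_genes": len(t),
        "n_regulated": len(regulated),
        "n_direct": len(direct),
        "n_direct_regulated": len(direct_reg),
        "pct_direct_regulated": _pct(len(direct_reg), len(direct)),
        "n_direct_regulated_down": len(dr_down),
        "pct_direct_regulated_down": _pct(len(dr_down), len(direct_reg)),
        "n_direct_unregulated": len(direct_unreg),
        "pct_direct_unregulated": _pct(len(direct_unreg), len(direct)),
        "n_indirect_regulated": len(indirect),
        "pct_indirect_of_regulated": _pct(len(indirect), len(regulated)),
        "n_indirect_up": len(ind_up),
        "pct_indirect_up": _pct(len(ind_up), len(indirect)),
        "n_indirect_down": len(ind_down),
        "pct_indirect_down": _pct(len(ind_down), len(indirect)),
        "n_indirect_protein_coding": len(ind_pc),
        "n_indirect_pc_up": len(ind_pc_up),
        "pct_indirect_pc_up": _pct(len(ind_pc_up), len(ind_pc)),
        "n_indirect_pc_down": len(ind_pc_down),
        "pct_indirect_pc_down": _pct(len(ind_pc_down), len(ind_pc)),
        "n_unaffected": int((t["target_class"] == "unaffected").sum()),
    }


def summarize_peak_classes(peak_table: pd.DataFrame) -> dict:
    """Peak and gene counts per class, with the control-total consistency.

    Control peaks partition into lost + overlapping (common/reduced count
    within the overlap), so n_control = n_lost + n_overlapping.
    """
    ctrl = peak_table[peak_table["condition"] == "control"]
    counts = ctrl["peak_class"].value_counts().to_dict()
    n_lost = int(counts.get("lost", 0))
    n_reduced = int(counts.get("reduced", 0))
    n_common = int(counts.get("common", 0))
    n_overlapping = int(len(ctrl) - n_lost)
    sil_only = peak_table[
        (peak_table["condition"] == "silenced")
        & (peak_table["peak_class"] == "independent")
    ]
    genes = lambda df: int(df["gene_id"].nunique())  # noqa: E731
    return {
        "n_control_peaks": int(len(ctrl)),
        "n_lost_peaks": n_lost,
        "n_lost_genes": genes(ctrl[ctrl["peak_class"] == "lost"]),
        "n_reduced_peaks": n_reduced,
        "n_reduced_genes": genes(ctrl[ctrl["peak_class"] == "reduced"]),
        "n_common_peaks": n_common,
        "n_common_genes": genes(ctrl[ctrl["peak_class"] == "common"]),
        "n_overlapping_peaks": n_overlapping,
        "n_independent_peaks": int(
            len(sil_only) + int(counts.get("independent", 0))
        ),
        "total_consistent": n_lost + n_overlapping == int(len(ctrl)),
    }


def cdf_compare(
    sample_a: Sequence[float], sample_b: Sequence[float], method: str = "ks"
) -> tuple[float, float, float]:
    """Two-sample distribution comparison: (statistic, p, median shift a-b)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "ks":
        res = stats.ks_2samp(a, b, method="asymp")
    elif method == "wilcoxon":
        res = stats.ranksums(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), float(
        np.median(a) - np.median(b)
    )


def classify_rbp(
    with_site_deltas: Sequence[float],
    without_site_deltas: Sequence[float],
    alpha: float = 0.05,
) -> str:
    """Label an RBP by its cooperation with m6A on transcript stability.

    ``*_deltas`` are per-gene expression changes (silenced - control) of
    m6A-modified transcripts with vs without a binding site for the RBP.
    Site-bearing transcripts dropping further -> the site stabilizes m6A
    transcripts ("stabilizer"); rising -> "destabilizer"; no significant
    distribution difference -> "neutral".
    """
    _, p, med_shift = cdf_compare(with_site_deltas, without_site_deltas)
    if p >= alpha:
        return "neutral"
    return "stabilizer" if med_shift < 0 else "destabilizer"


def abundance_by_group(
    expression: pd.DataFrame,
    biotypes: Sequence[str] = ("protein_coding", "lincRNA"),
) -> dict:
    """Abundance CDF tables and KS tests for m6A vs non-m6A per biotype.

    ``expression`` needs columns gene_id, abundance, m6a (bool), biotype.
    Raises on an empty biotype group; a biotype with only one m6A status
    yields its CDF without a test.
    """
    out: dict = {}
    for bt in biotypes:
        sub = expression[expression["biotype"] == bt]
        if sub.empty:
            raise ValueError(f"no genes with biotype {bt!r}")
        grp: dict = {"cdf": {}}
        for flag, label in ((True, "m6a"), (False, "non_m6a")):
            vals = np.sort(sub.loc[sub["m6a"] == flag, "abundance"].to_numpy())
            if vals.size:
                grp["cdf"][label] = pd.DataFrame(
                    {
                        "abundance": vals,
                        "cum_fraction": np.arange(1, vals.size + 1) / vals.size,
                    }
                )
        if len(grp["cdf"]) == 2:
            d, p, shift = cdf_compare(
                sub.loc[sub["m6a"], "abundance"],
                sub.loc[~sub["m6a"], "abundance"],
            )
            grp["ks"] = {"D": d, "p": p, "median_shift": shift}
        else:
            log.warning("biotype %s has a single m6A group; CDF only", bt)
        out[bt] = grp
    return out
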