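"""Metagene summaries of peak positions over a rescaled transcript model.

Coding transcripts are divided into 5'UTR, CDS and 3'UTR segments and every
peak position is mapped to x in [0,3): [0,1) spans the 5'UTR, [1,2) the CDS
and [2,3) the 3'UTR, each segment rescaled to unit length.  x = 2 is the stop
codon boundary.  Noncoding transcripts have no segment structure and are
excluded from the rescaled profile (they still take part in peak calling).

The module also reports the stop-codon-relative summit offset, peaks-per-gene
counts, and the association between peak enrichment score and the number of
m6A consensus sites (default motif RRAC, IUPAC-matched) within the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .peaks import Peak

log = logging.getLogger(__name__)

__all__ = [
    "MetagenePosition",
    "rescale_position",
    "stop_offset",
    "peaks_per_gene",
    "count_motif",
    "score_vs_motif_count",
    "metagene_histogram",
    "metagene_table",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class MetagenePosition:
    transcript_id: str
    tpos: int
    x: float
    region_class: str


def rescale_position(tpos: int, model: GeneModel) -> float | None:
    """Map a transcript position to x in [0,3) over rescaled segments.

    Returns None for noncoding models (no 3-segment structure).
    """
    if not model.is_coding:
        return None
    if not 0 <= tpos < model.transcript_length:
        raise ValueError(f"tpos {tpos} outside transcript {model.transcript_id}")
    segments = (
        (0, model.utr5_len),
        (model.cds_start_tx, model.cds_len),
        (model.cds_end_tx, model.utr3_len),
    )
    for i, (seg_start, seg_len) in enumerate(segments):
        if seg_len and tpos < seg_start + seg_len:
            return i + (tpos - seg_start) / seg_len
    # only reachable when the 3'UTR is empty and tpos == cds_end_tx - eps
    return 2.0


def _region_of_x(x: float) -> str:
    return "5'UTR" if x < 1 else ("CDS" if x < 2 else "3'UTR")


def stop_offset(summit: int, model: GeneModel) -> int | None:
    """Signed nt distance of the summit from the stop codon (negative = upstream)."""
    if not model.is_coding:
        return None
    return summit - model.cds_end_tx


def metagene_table(
    peaks: Sequence[Peak],
    models: Mapping[str, GeneModel],
    position: str = "midpoint",
) -> pd.DataFrame:
    """Rescaled positions and stop offsets for all peaks on coding models.

    ``position`` selects the representative peak coordinate ("midpoint",
    default, or "summit").
    """
    if position not in {"midpoint", "summit"}:
        raise ValueError("position must be 'midpoint' or 'summit'")
    tx_models = {m.transcript_id: m for m in models.values()}
    rows = []
    for p in peaks:
        model = tx_models.get(p.transcript_id)
        if model is None or not model.is_coding:
            continue
        tpos = p.midpoint if position == "midpoint" else p.summit
        tpos = min(tpos, model.transcript_length - 1)
        x = rescale_position(tpos, model)
        rows.append(
            {
                "transcript_id": p.transcript_id,
                "gene_id": p.gene_id or model.gene_id,
                "tpos": tpos,
                "x": x,
                "region_class": _region_of_x(x),
                "stop_offset": stop_offset(p.summit, model),
                "enrichment_score": p.enrichment_score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "tpos", "x", "region_class",
            "stop_offset", "enrichment_score",
        ],
    )


def metagene_histogram(
    xs: Sequence[float], bins: int | Sequence[float] = 30
) -> pd.DataFrame:
    """Histogram of rescaled positions over [0,3).

    ``bins`` may be a count or explicit edges; edges not divisible by 3
    place the stop-codon boundary (x = 2) in a bin interior, which pools
    enrichment from both flanks of the stop codon into one bin.
    """
    edges = (
        np.linspace(0.0, 3.0, int(bins) + 1)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    counts, edges = np.histogram(np.asarray(xs, dtype=float), bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def peaks_per_gene(peaks: Sequence[Peak]) -> tuple[pd.Series, float | None]:
    """Histogram of peak counts over peak-bearing genes and the one-peak fraction."""
    genes = pd.Series(
        [p.gene_id or p.transcript_id for p in peaks], dtype="object"
    )
    if genes.empty:
        return pd.Series(dtype=int), None
    per_gene = genes.value_counts()
    hist = per_gene.value_counts().sort_index()
    fraction_one = float((per_gene == 1).sum() / per_gene.size)
    return hist, fraction_one


def count_motif(sequence: str, motif: str = "RRAC") -> int:
    """Number of (possibly overlapping) IUPAC motif matches in a sequence."""
    seq = sequence.upper().replace("U", "T")
    sets = [IUPAC[b] for b in motif.upper()]
    k = len(sets)
    return sum(
        all(seq[i + j] in sets[j] for j in range(k))
        for i in range(len(seq) - k + 1)
    )


def score_vs_motif_count(
    scores: Sequence[float],
    sequences: Sequence[str],
    motif: str = "RRAC",
) -> tuple[float | None, float | None, list[int]]:
    """Spearman correlation of peak enrichment score vs consensus-site count.

    Returns (rho, p, counts); rho/p are None when ranks are degenerate
    (e.g. identical scores across peaks).
    """
    if len(scores) != len(sequences):
        raise ValueError("scores and sequences must be parallel")
    counts = [count_motif(s, motif) for s in sequences]
    if len(scores) < 3 or len(set(scores)) < 2 or len(set(counts)) < 2:
        log.warning("degenerate input for rank correlation; returning None")
        return None, None, counts
    rho, p = stats.spearmanr(scores, counts)
    return float(rho), float(p), counts
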