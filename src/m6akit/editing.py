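"""RNA-editing candidate filtering, typing and annotation.

Candidate mismatch sites (from an upstream variant caller, supplied with the
0-based offset of the mismatch within each supporting read) pass through an
ordered filter cascade:

1. known-SNP removal (all sites);
2. support discounting - mismatches at read offsets 0-5 are discarded
   (random-hexamer priming artifacts) before counting alt reads;
then, for non-Alu sites only (Alu elements host the bulk of genuine A-to-I
editing and skip these steps unless ``strict_all``):
3. support: >= 3 effective alt reads and alt frequency >= 0.1;
4. simple-repeat mask;
5. within 4 bp of a known splice junction;
6. reference homopolymer run >= 5 nt covering the site;
7. high-similarity (multi-mapping) region mask.

``filter_status`` records the first failing filter; survivors are "pass".
High-confidence events have >= 10 total reads and editing ratio >= 0.2
(both inclusive).  A-to-I events appear as A->G on the transcript strand
(T->C genomic on minus-strand genes), C-to-U as C->T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .annotation import GeneModel, IntervalMask

log = logging.getLogger(__name__)

__all__ = [
    "EditingSite",
    "filter_cascade",
    "homopolymer_check",
    "high_confidence",
    "classify_edit_type",
    "annotate_region",
    "compare_editing",
]

READ_PRIME_DISCARD = 6  # first read bases whose mismatches are discounted
REQUIRED_MASKS = ("snp", "alu", "simple_repeat", "splice_junction", "similarity")
COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class EditingSite:
    chrom: str
    pos: int  # 0-based genomic
    ref_base: str
    alt_base: str
    strand: str = "."  # host-gene strand, '.' if intergenic/unknown
    total_reads: int = 0
    alt_read_offsets: tuple[int, ...] = ()
    in_alu: bool = False
    region: str = "unknown"
    codon_effect: str = "none"
    filter_status: str = "unfiltered"
    edit_type: str = "other"

    def __post_init__(self) -> None:
        self.alt_read_offsets = tuple(int(o) for o in self.alt_read_offsets)
        if len(self.alt_read_offsets) > self.total_reads:
            raise ValueError("more alt reads than total reads")

    @property
    def alt_reads(self) -> int:
        """Effective alt support after discounting the first read bases."""
        return sum(1 for o in self.alt_read_offsets if o >= READ_PRIME_DISCARD)

    @property
    def editing_ratio(self) -> float:
        return self.alt_reads / self.total_reads if self.total_reads else 0.0

    @property
    def high_confidence(self) -> bool:
        return high_confidence(self)


def high_confidence(site: EditingSite) -> bool:
    """>= 10 supporting reads and editing ratio >= 0.2, both inclusive."""
    return site.total_reads >= 10 and site.editing_ratio >= 0.2


def homopolymer_check(
    site: EditingSite, reference: Mapping[str, str], min_run: int = 5
) -> bool:
    """True iff the reference run of identical bases covering the site
    has length >= ``min_run`` (a run merely adjacent to the site does not
    count)."""
    seq = reference[site.chrom]
    base = seq[site.pos]
    lo = site.pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = site.pos + 1
    while hi < len(seq) and seq[hi] == base:
        hi += 1
    return hi - lo >= min_run


def classify_edit_type(ref: str, alt: str, strand: str = ".") -> str:
    """A_to_I / C_to_U / other from the genomic base change and gene strand.

    Stranded sites are evaluated on the transcript strand; strandless sites
    are typed by the genomic change with both orientations admitted
    (A->G or T->C -> A_to_I; C->T or G->A -> C_to_U).
    """
    ref, alt = ref.upper(), alt.upper()
    if strand == "-":
        ref = ref.translate(COMPLEMENT)
        alt = alt.translate(COMPLEMENT)
    pair = (ref, alt)
    if strand in {"+", "-"}:
        if pair == ("A", "G"):
            return "A_to_I"
        if pair == ("C", "T"):
            return "C_to_U"
        return "other"
    if pair in {("A", "G"), ("T", "C")}:
        return "A_to_I"
    if pair in {("C", "T"), ("G", "A")}:
        return "C_to_U"
    return "other"


def filter_cascade(
    sites: Sequence[EditingSite],
    masks: Mapping[str, IntervalMask],
    reference: Mapping[str, str],
    min_alt_reads: int = 3,
    min_alt_freq: float = 0.1,
    junction_dist: int = 4,
    homopolymer_len: int = 5,
    strict_all: bool = False,
) -> list[EditingSite]:
    """Apply the ordered filter cascade; sets filter_status/in_alu/edit_type.

    The per-site outcome is independent of input order.  Missing masks raise
    KeyError naming the mask.
    """
    for name in REQUIRED_MASKS:
        if name not in masks:
            raise KeyError(f"missing interval mask: {name!r}")
    for site in sites:
        site.edit_type = classify_edit_type(site.ref_base, site.alt_base, site.strand)
        site.in_alu = masks["alu"].contains(site.chrom, site.pos)
        site.filter_status = _site_status(
            site, masks, reference, min_alt_reads, min_alt_freq,
            junction_dist, homopolymer_len, strict_all,
        )
    return list(sites)


def _site_status(
    site: EditingSite,
    masks: Mapping[str, IntervalMask],
    reference: Mapping[str, str],
    min_alt_reads: int,
    min_alt_freq: float,
    junction_dist: int,
    homopolymer_len: int,
    strict_all: bool,
) -> str:
    if masks["snp"].contains(site.chrom, site.pos):
        return "snp"
    if site.in_alu and not strict_all:
        return "pass"
    if site.alt_reads < min_alt_reads or site.editing_ratio < min_alt_freq:
        return "support"
    if masks["simple_repeat"].contains(site.chrom, site.pos):
        return "simple_repeat"
    if masks["splice_junction"].within(site.chrom, site.pos, junction_dist):
        return "splice_junction"
    if homopolymer_check(site, reference, homopolymer_len):
        return "homopolymer"
    if masks["similarity"].contains(site.chrom, site.pos):
        return "similarity"
    return "pass"


def annotate_region(
    site: EditingSite,
    models: Mapping[str, GeneModel],
    reference: Mapping[str, str] | None = None,
) -> EditingSite:
    """Assign region (CDS/UTR/intronic/intergenic) and codon effect.

    Precedence: CDS > UTR > intronic > intergenic across all overlapping
    models.  Codon effects substitute the alt base into the reference codon
    under the standard genetic code (requires ``reference``).
    """
    best_rank = 5
    best: tuple[str, str] = ("intergenic", "none")
    for model in models.values():
        if model.chrom != site.chrom:
            continue
        lo, hi = model.span
        if not lo <= site.pos < hi:
            continue
        tpos = model.genome_to_transcript(site.pos)
        if tpos is None:
            rank, region, effect = 3, "intronic", "none"
        elif model.is_coding and model.cds_start_tx <= tpos < model.cds_end_tx:
            rank, region = 1, "exonic"
            effect = (
                _codon_effect(site, model, tpos, reference)
                if reference is not None
                else "none"
            )
        elif model.is_coding and tpos < model.cds_start_tx:
            rank, region, effect = 2, "5'UTR", "none"
        elif model.is_coding:
            rank, region, effect = 2, "3'UTR", "none"
        else:
            rank, region, effect = 2, "exonic", "none"
        if rank < best_rank:
            best_rank, best = rank, (region, effect)
    site.region, site.codon_effect = best
    return site


def _codon_effect(
    site: EditingSite,
    model: GeneModel,
    tpos: int,
    reference: Mapping[str, str],
) -> str:
    txseq = model.transcript_sequence(reference)
    cds_off = tpos - model.cds_start_tx
    codon_start = model.cds_start_tx + 3 * (cds_off // 3)
    codon = txseq[codon_start:codon_start + 3]
    if len(codon) < 3:
        return "none"
    alt = site.alt_base.upper()
    if model.strand == "-":
        alt = alt.translate(COMPLEMENT)
    mutated = list(codon)
    mutated[cds_off % 3] = alt
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(mutated)).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _ratio_array(sites: Sequence[EditingSite]) -> np.ndarray:
    return np.array([s.editing_ratio for s in sites], dtype=float)


def compare_editing(
    sites_a: Sequence[EditingSite],
    sites_b: Sequence[EditingSite],
    ratio_threshold: float = 0.2,
) -> dict:
    """Between-condition editing summary at an editing-ratio threshold.

    Counts events with ratio >= threshold in each condition, the percentage
    change from a to b, per-type counts/proportions, and KS comparisons of
    the editing-ratio distributions overall and per type.
    """
    a = [s for s in sites_a if s.editing_ratio >= ratio_threshold]
    b = [s for s in sites_b if s.editing_ratio >= ratio_threshold]
    out: dict = {
        "n_a": len(a),
        "n_b": len(b),
        "pct_change": (100.0 * (len(a) - len(b)) / len(a)) if a else None,
        "by_type": {},
    }
    types = sorted({s.edit_type for s in a} | {s.edit_type for s in b})
    for t in types:
        ta = [s for s in a if s.edit_type == t]
        tb = [s for s in b if s.edit_type == t]
        entry = {
            "n_a": len(ta),
            "n_b": len(tb),
            "prop_a": len(ta) / len(a) if a else None,
            "prop_b": len(tb) / len(b) if b else None,
        }
        if len(ta) >= 2 and len(tb) >= 2:
            res = stats.ks_2samp(_ratio_array(ta), _ratio_array(tb), method="asymp")
            entry["ks_p"] = float(res.pvalue)
        out["by_type"][t] = entry
    if len(a) >= 2 and len(b) >= 2:
        res = stats.ks_2samp(_ratio_array(a), _ratio_array(b), method="asymp")
        out["ks_D"], out["ks_p"] = float(res.statistic), float(res.pvalue)
    return out


def sites_to_dataframe(sites: Sequence[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "strand": s.strand,
                "total_reads": s.total_reads,
                "alt_reads": s.alt_reads,
                "editing_ratio": s.editing_ratio,
                "in_alu": s.in_alu,
                "region": s.region,
                "codon_effect": s.codon_effect,
                "edit_type": s.edit_type,
                "filter_status": s.filter_status,
                "high_confidence": s.high_confidence,
            }
            for s in sites
        ]
    )
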