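"""Gene models, interval masks and genome/transcript coordinate projection.

Transcript architectures are represented by :class:`GeneModel`, which keeps the
exon chain in genomic coordinates together with the CDS span in transcript
coordinates.  All internal coordinates are 0-based half-open; GTF input
(1-based inclusive) is converted on read, BED input is passed through.

"Longest isoform" selection measures summed exon length (not genomic span),
with ties broken by the lexicographically smallest transcript id, so the
choice is deterministic.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "IntervalMask",
    "read_gtf",
    "select_longest_isoform",
    "load_gene_models",
    "read_bed_mask",
    "write_models_tsv",
]


@dataclass
class GeneModel:
    """A single transcript architecture in genome and transcript coordinates.

    ``exons`` are genomic 0-based half-open intervals, non-overlapping and
    sorted by genomic start regardless of strand.  ``cds_start_tx`` /
    ``cds_end_tx`` delimit the CDS in transcript coordinates (half-open); a
    noncoding transcript carries ``cds_start_tx == cds_end_tx``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_tx: int = 0
    cds_end_tx: int = 0
    biotype: str = "protein_coding"
    # cumulative exon lengths, filled in __post_init__
    _offsets: tuple[int, ...] = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in exons:
            if b <= a:
                raise ValueError(f"empty exon {(a, b)} in {self.transcript_id}")
        for (_, b), (a2, _) in zip(exons, exons[1:]):
            if a2 < b:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.exons = exons
        offs = [0]
        for a, b in exons:
            offs.append(offs[-1] + (b - a))
        self._offsets = tuple(offs)
        if not (0 <= self.cds_start_tx <= self.cds_end_tx <= self.transcript_length):
            raise ValueError(
                f"CDS span [{self.cds_start_tx},{self.cds_end_tx}) outside "
                f"transcript of length {self.transcript_length}"
            )

    @property
    def transcript_length(self) -> int:
        return self._offsets[-1]

    @property
    def is_coding(self) -> bool:
        return self.cds_end_tx > self.cds_start_tx

    @property
    def utr5_len(self) -> int:
        return self.cds_start_tx if self.is_coding else 0

    @property
    def cds_len(self) -> int:
        return self.cds_end_tx - self.cds_start_tx

    @property
    def utr3_len(self) -> int:
        return self.transcript_length - self.cds_end_tx if self.is_coding else 0

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    # -- coordinate projection -------------------------------------------------

    def genome_to_transcript(self, gpos: int) -> int | None:
        """5'->3' transcript offset of genomic position ``gpos``.

        Returns None for intronic/intergenic positions.  Minus-strand
        transcripts count from the genomic right end, so the rightmost exonic
        base is transcript position 0.
        """
        i = bisect.bisect_right([a for a, _ in self.exons], gpos) - 1
        if i < 0 or gpos >= self.exons[i][1]:
            return None
        plus_off = self._offsets[i] + (gpos - self.exons[i][0])
        if self.strand == "+":
            return plus_off
        return self.transcript_length - 1 - plus_off

    def transcript_to_genome(self, tpos: int) -> int:
        """Inverse projection; round-trips with :meth:`genome_to_transcript`."""
        if not 0 <= tpos < self.transcript_length:
            raise ValueError(
                f"tpos {tpos} outside [0,{self.transcript_length}) of "
                f"{self.transcript_id}"
            )
        plus_off = tpos if self.strand == "+" else self.transcript_length - 1 - tpos
        i = bisect.bisect_right(self._offsets, plus_off) - 1
        return self.exons[i][0] + (plus_off - self._offsets[i])

    def transcript_interval_to_genome(
        self, start: int, end: int
    ) -> list[tuple[int, int]]:
        """Project a transcript interval to (possibly split) genomic blocks."""
        if not 0 <= start < end <= self.transcript_length:
            raise ValueError(f"bad transcript interval [{start},{end})")
        gpos = sorted(self.transcript_to_genome(t) for t in (start, end - 1))
        lo, hi = gpos[0], gpos[1] + 1
        blocks = []
        for a, b in self.exons:
            s, e = max(a, lo), min(b, hi)
            if s < e:
                blocks.append((s, e))
        return blocks

    def transcript_sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced transcript sequence (5'->3') from a chrom->sequence mapping."""
        from Bio.Seq import Seq

        chunks = [genome[self.chrom][a:b] for a, b in self.exons]
        seq = "".join(chunks)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


class IntervalMask:
    """A named set of genomic intervals with O(log n) point queries.

    Used for the editing filter masks (Alu, simple repeats, known SNPs,
    splice junctions, similarity regions).
    """

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]] = ()):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"empty interval [{start},{end}) in mask {self.name}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree and tree.overlaps_point(pos))

    def within(self, chrom: str, pos: int, dist: int) -> bool:
        """True if any interval lies within ``dist`` nt of ``pos`` (gap <= dist)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos - dist, pos + dist + 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# -- GTF / BED / TSV I/O -------------------------------------------------------


def _parse_gtf_db(db: "gffutils.FeatureDB") -> list[GeneModel]:
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS"}:
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError:
            log.warning("feature without gene_id/transcript_id skipped: %s", feat)
            continue
        rec = by_tx.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": (feat.attributes.get("gene_type") or ["protein_coding"])[0],
                "exons": [],
                "cds": [],
            },
        )
        # GTF is 1-based inclusive; convert to 0-based half-open
        iv = (feat.start - 1, feat.end)
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)

    models = []
    for tid, rec in by_tx.items():
        if not rec["exons"]:
            log.warning("transcript %s has no exon features; skipped", tid)
            continue
        model = GeneModel(
            gene_id=rec["gene_id"],
            transcript_id=tid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        if rec["cds"]:
            gstarts = [a for a, _ in rec["cds"]]
            gends = [b for _, b in rec["cds"]]
            t1 = model.genome_to_transcript(min(gstarts))
            t2 = model.genome_to_transcript(max(gends) - 1)
            if t1 is None or t2 is None:
                log.warning("CDS of %s outside exons; treated as noncoding", tid)
            else:
                lo, hi = sorted((t1, t2))
                model = GeneModel(
                    gene_id=rec["gene_id"],
                    transcript_id=tid,
                    chrom=rec["chrom"],
                    strand=rec["strand"],
                    exons=tuple(rec["exons"]),
                    cds_start_tx=lo,
                    cds_end_tx=hi + 1,
                    biotype=rec["biotype"],
                )
        models.append(model)
    return models


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a Gencode-dialect GTF into one GeneModel per transcript."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    return _parse_gtf_db(db)


def select_longest_isoform(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    """One model per gene: longest summed exon length, ties by transcript id."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.transcript_length > cur.transcript_length
            or (
                m.transcript_length == cur.transcript_length
                and m.transcript_id < cur.transcript_id
            )
        ):
            best[m.gene_id] = m
    return best


def load_gene_models(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Read a GTF and keep the longest isoform of every gene."""
    return select_longest_isoform(read_gtf(gtf_path))


def read_bed_mask(path: str | Path, name: str) -> IntervalMask:
    """Read a BED3+ file into an IntervalMask (coordinates passed through)."""
    mask = IntervalMask(name)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            mask.add(parts[0], int(parts[1]), int(parts[2]))
    return mask


def write_models_tsv(models: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttranscript_id\tchrom\tstrand\ttranscript_length\t"
            "cds_start_tx\tcds_end_tx\tbiotype\texons\n"
        )
        for gid in sorted(models):
            m = models[gid]
            exons = ",".join(f"{a}-{b}" for a, b in m.exons)
            fh.write(
                f"{gid}\t{m.transcript_id}\t{m.chrom}\t{m.strand}\t"
                f"{m.transcript_length}\t{m.cds_start_tx}\t{m.cds_end_tx}\t"
                f"{m.biotype}\t{exons}\n"
            )


def write_gtf(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models back out as a minimal Gencode-dialect GTF."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "{m.biotype}";'
            )
            for a, b in m.exons:
                fh.write(
                    f"{m.chrom}\tm6akit\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.is_coding:
                for a, b in m.transcript_interval_to_genome(
                    m.cds_start_tx, m.cds_end_tx
                ):
                    fh.write(
                        f"{m.chrom}\tm6akit\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t{attrs}\n"
                    )
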