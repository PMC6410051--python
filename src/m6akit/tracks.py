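"""Per-nucleotide coverage tracks on transcript coordinates.

A :class:`CoverageTrack` holds the read coverage of one library over one
transcript, together with the library's total read count (used for the
per-million normalization of the visualization tracks).  Tracks are stored
and exchanged as plain per-base TSV (transcript_id, pos, coverage), the
format the rest of the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["CoverageTrack", "read_tracks_tsv", "write_tracks_tsv", "normalize_track"]


@dataclass
class CoverageTrack:
    transcript_id: str
    values: np.ndarray  # per-nt read coverage, length = transcript length
    library_size: int  # total reads in the library

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage must be one-dimensional")
        if (self.values < 0).any():
            raise ValueError("negative coverage")

    def __len__(self) -> int:
        return self.values.size


def normalize_track(values: np.ndarray, total_reads: int) -> np.ndarray:
    """Scale per-nt coverage to reads-per-million of the library.

    Positive scaling, so summit (argmax) positions are invariant.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return np.asarray(values, dtype=float) * 1e6 / total_reads


def write_tracks_tsv(
    tracks: Mapping[str, CoverageTrack], path: str | Path
) -> None:
    """Write tracks as per-base TSV with the library size in a header comment."""
    sizes = {t.library_size for t in tracks.values()}
    libsize = max(sizes) if sizes else 0
    with open(path, "w") as fh:
        fh.write(f"# library_size={libsize}\n")
        fh.write("transcript_id\tpos\tcoverage\n")
        for tid in sorted(tracks):
            vals = tracks[tid].values
            for pos, v in enumerate(vals):
                fh.write(f"{tid}\t{pos}\t{v:g}\n")


def read_tracks_tsv(path: str | Path) -> dict[str, CoverageTrack]:
    libsize = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# library_size="):
            libsize = int(float(first.strip().split("=", 1)[1]))
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    tracks: dict[str, CoverageTrack] = {}
    for tid, sub in df.groupby("transcript_id", sort=True):
        sub = sub.sort_values("pos")
        n = int(sub["pos"].max()) + 1
        vals = np.zeros(n)
        vals[sub["pos"].to_numpy(dtype=int)] = sub["coverage"].to_numpy(dtype=float)
        tracks[str(tid)] = CoverageTrack(str(tid), vals, libsize)
    return tracks


def make_tracks(
    coverages: Mapping[str, np.ndarray], read_length: int = 50
) -> dict[str, CoverageTrack]:
    """Bundle raw coverage arrays into tracks with a derived library size."""
    total = sum(float(np.sum(v)) for v in coverages.values())
    libsize = max(int(round(total / read_length)), 1)
    return {
        tid: CoverageTrack(tid, np.asarray(v, dtype=float), libsize)
        for tid, v in coverages.items()
    }
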