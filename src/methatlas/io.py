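"""Readers and writers for per-CpG methylation tracks, BED files and matrices.

The per-CpG format is a 6-column tab-delimited table, one row per CpG::

    chrom  pos  strand  context  level  reads

``pos`` is 0-based.  ``level`` is the methylated-read fraction in [0, 1];
``reads`` is coverage.  A CpG with ``reads == 0`` carries an undefined level
(written/parsed as ``nan``) and is excluded from every mean — it is never
treated as 0% methylation.  CpGs are assumed symmetric (strand-merged) by
default; the strand column is preserved but not interpreted.

gzip is handled transparently on read and write (``.gz`` suffix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "MethylomeTrack",
    "read_methylome",
    "write_methylome",
    "read_bed",
    "write_bed",
    "export_browser_track",
    "read_matrix",
    "write_matrix",
]

log = logging.getLogger(__name__)

_COLUMNS = ["chrom", "pos", "strand", "context", "level", "reads"]


@dataclass
class MethylomeTrack:
    """A per-sample methylome: per-CpG levels and coverage, genome-ordered."""

    sample_id: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"track missing columns: {missing}")
        self.df = self.df.sort_values(["chrom", "pos"], kind="stable").reset_index(
            drop=True
        )
        dup = self.df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError(
                f"duplicate CpG positions in track {self.sample_id!r} "
                f"(first at row {int(np.flatnonzero(dup.to_numpy())[0])})"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeTrack):
            return NotImplemented
        return self.sample_id == other.sample_id and self.df.equals(other.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(positions, levels, reads)`` for one chromosome, position-sorted."""
        sub = self.df[self.df["chrom"] == chrom]
        return (
            sub["pos"].to_numpy(np.int64),
            sub["level"].to_numpy(float),
            sub["reads"].to_numpy(np.int64),
        )

    def assessable(self) -> pd.DataFrame:
        """Rows with at least one read (defined methylation level)."""
        return self.df[self.df["reads"] > 0]


def read_methylome(path, sample_id: str | None = None) -> MethylomeTrack:
    """Parse a 6-column per-CpG file into a :class:`MethylomeTrack`.

    Malformed rows raise ``ValueError`` naming the (1-based) file line.
    An empty file yields an empty track with a logged warning.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=_COLUMNS,
            header=None,
            comment="#",
            dtype={"chrom": str, "strand": str, "context": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_COLUMNS)
    if len(df) == 0:
        log.warning("empty methylome file: %s", path)
        df = df.astype(
            {"pos": np.int64, "level": float, "reads": np.int64}, errors="ignore"
        )
        return MethylomeTrack(sample_id or str(path), df)

    pos = pd.to_numeric(df["pos"], errors="coerce")
    level = pd.to_numeric(df["level"], errors="coerce")
    reads = pd.to_numeric(df["reads"], errors="coerce")

    def _first_bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            line = int(mask.idxmax()) + 1
            raise ValueError(f"{path}: line {line}: {what}")

    _first_bad(pos.isna() | (pos < 0) | (pos != pos.round()), "bad position")
    _first_bad(reads.isna() | (reads < 0), "negative or non-numeric read count")
    has_reads = reads > 0
    _first_bad(
        has_reads & (level.isna() | (level < 0) | (level > 1)),
        "methylation level outside [0, 1]",
    )
    df = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": pos.astype(np.int64),
            "strand": df["strand"].astype(str),
            "context": df["context"].astype(str),
            "level": level.where(has_reads, np.nan).astype(float),
            "reads": reads.astype(np.int64),
        }
    )
    return MethylomeTrack(sample_id or str(path), df)


def write_methylome(track: MethylomeTrack, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    track.df.to_csv(path, sep="\t", header=False, index=False,
                    float_format="%.17g")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6 into an :class:`IntervalSet` (order preserved)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return IntervalSet()
    ivs = []
    for i, row in enumerate(df.itertuples(index=False)):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if start >= end:
            raise ValueError(f"{path}: line {i + 1}: start >= end ({start} >= {end})")
        name = str(row[3]) if len(row) > 3 and not pd.isna(row[3]) else None
        score = float(row[4]) if len(row) > 4 and not pd.isna(row[4]) else None
        ivs.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return IntervalSet(ivs)


def write_bed(intervals: IntervalSet, path) -> None:
    """Write BED3 (or BED5 when any interval carries a name/score)."""
    extended = any(iv.name is not None or iv.score is not None for iv in intervals)
    with _open_write(path) as fh:
        for iv in intervals:
            if extended:
                name = iv.name if iv.name is not None else "."
                score = repr(iv.score) if iv.score is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def export_browser_track(track: MethylomeTrack, path, name: str | None = None) -> None:
    """bedGraph export for genome browsers.

    Each covered CpG gets score ``level - 0.5`` (range -0.5..0.5): positive
    scores mark hypermethylated sites (>50% methylation, upward bars) and
    negative scores hypomethylated ones.  Zero-coverage CpGs are omitted.
    """
    label = name or track.sample_id
    with _open_write(path) as fh:
        fh.write(f'track type=bedGraph name="{label}"\n')
        sub = track.assessable()
        for chrom, pos, level in zip(sub["chrom"], sub["pos"], sub["level"]):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{level - 0.5:.6g}\n")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def _open_write(path):
    import gzip

    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")
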