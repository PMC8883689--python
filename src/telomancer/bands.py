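"""Mapping copy-number segments onto cytogenetic bands.

Supports band-level enrichment analyses (e.g. locating a minimal amplified
region on a chromosome arm): per-sample amplified segments are intersected
with a cytoband table and any band overlapped by at least ``min_overlap``
base pairs of an amplified segment is called amplified for that sample.

All internal coordinates are 0-based half-open (BED convention); readers
accept 1-based inclusive input behind an explicit flag.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

logger = logging.getLogger(__name__)

AMPLIFIED = "amplified"
NEUTRAL = "neutral"
DELETED = "deleted"
_STATUSES = frozenset({AMPLIFIED, NEUTRAL, DELETED})


@dataclass(frozen=True)
class CNSegment:
    """One copy-number segment, 0-based half-open."""

    chrom: str
    start: int
    end: int
    status: str = AMPLIFIED

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )
        if self.status not in _STATUSES:
            raise ValueError(f"unknown segment status {self.status!r}")


@dataclass(frozen=True)
class CytoBand:
    """One cytogenetic band, 0-based half-open."""

    chrom: str
    start: int
    end: int
    band_label: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"band {self.band_label}: require 0 <= start < end"
            )


@dataclass(frozen=True)
class BandCallSet:
    """Per-sample set of amplified band labels."""

    sample_id: str
    amplified_bands: frozenset[str]


class _BandIndex:
    """Per-chromosome sorted band arrays for fast interval lookup.

    Bands on a chromosome must be non-overlapping and sorted; validated on
    construction.
    """

    def __init__(self, bands: Sequence[CytoBand]):
        self.by_chrom: Dict[str, List[CytoBand]] = {}
        for b in bands:
            self.by_chrom.setdefault(b.chrom, []).append(b)
        self.starts: Dict[str, List[int]] = {}
        self.ends: Dict[str, List[int]] = {}
        for chrom, bb in self.by_chrom.items():
            bb.sort(key=lambda b: b.start)
            for prev, cur in zip(bb, bb[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping bands on {chrom}: {prev.band_label}, {cur.band_label}"
                    )
            self.starts[chrom] = [b.start for b in bb]
            self.ends[chrom] = [b.end for b in bb]

    def overlapping(self, chrom: str, start: int, end: int) -> List[CytoBand]:
        bb = self.by_chrom.get(chrom)
        if not bb:
            return []
        lo = bisect_right(self.ends[chrom], start)   # first band with band.end > start
        hi = bisect_left(self.starts[chrom], end)    # bands with band.start < end
        return bb[lo:hi]


def call_amplified_bands(
    sample_id: str,
    segments: Iterable[CNSegment],
    bands: Sequence[CytoBand],
    min_overlap: int = 1,
) -> BandCallSet:
    """Call a band amplified iff >= ``min_overlap`` bp of an amplified segment overlaps it.

    Segments on chromosomes absent from the band table are ignored with a
    logged warning; non-amplified segments never produce calls.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    index = _BandIndex(bands)
    called: set[str] = set()
    for seg in segments:
        if seg.status != AMPLIFIED:
            continue
        if seg.chrom not in index.by_chrom:
            logger.warning(
                "sample %s: segment chromosome %r not in band table; ignored",
                sample_id,
                seg.chrom,
            )
            continue
        for band in index.overlapping(seg.chrom, seg.start, seg.end):
            overlap = min(seg.end, band.end) - max(seg.start, band.start)
            if overlap >= min_overlap:
                called.add(band.band_label)
    return BandCallSet(sample_id=sample_id, amplified_bands=frozenset(called))


def gene_to_band(
    interval: CNSegment,
    bands: Sequence[CytoBand],
) -> List[str]:
    """Labels of all bands overlapping a genomic interval, in genomic order."""
    index = _BandIndex(bands)
    return [b.band_label for b in index.overlapping(interval.chrom, interval.start, interval.end)]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_cytobands(path: Union[str, Path]) -> List[CytoBand]:
    """Read a BED-like 4+ column cytoband table (UCSC cytoBand layout)."""
    out: List[CytoBand] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, label = line.split("\t")[:4]
            out.append(CytoBand(chrom, int(start), int(end), label))
    return out


def read_segments(
    path: Union[str, Path], one_based: bool = False
) -> Dict[str, List[CNSegment]]:
    """Read a headered TSV (sample_id, chrom, start, end, status) into per-sample lists.

    With ``one_based=True`` coordinates are interpreted as 1-based inclusive
    (as in printed gene intervals, e.g. "chr8:117858173-117887105") and
    converted to 0-based half-open.
    """
    out: Dict[str, List[CNSegment]] = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("sample_id", "chrom", "start", "end", "status"):
            if col not in idx:
                raise ValueError(f"segments file missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[idx["start"]])
            end = int(f[idx["end"]])
            if one_based:
                start -= 1
            out.setdefault(f[idx["sample_id"]], []).append(
                CNSegment(f[idx["chrom"]], start, end, f[idx["status"]])
            )
    return out
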