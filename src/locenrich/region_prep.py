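"""Prepare equal-length sequence windows from genomic files.

Supports the two study designs the statistics expect: fixed-size
windows centered on ChIP-seq peak midpoints (narrowPeak input), and
TSS-centered promoter windows split into "bound" and "unbound" sets by
proximity to a declared peak.  Sequences are extracted from an indexed
genome FASTA via pyfaidx.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from pyfaidx import Fasta

from .sequence_io import SequenceSet

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")

DEFAULT_WINDOW = 500
DEFAULT_TSS_RADIUS = 1000


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: Optional[float] = None
    summit: Optional[int] = None  # offset from start, narrowPeak column 10

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read an ENCODE narrowPeak (BED6+4) file."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path} line {lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            peak = int(fields[9])
            intervals.append(
                GenomicInterval(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else ".",
                    name=name,
                    score=float(score),
                    summit=peak if peak >= 0 else None,
                )
            )
    return intervals


def read_bed6(path) -> list[GenomicInterval]:
    """Read a BED6 file (e.g. a TSS table, 1 bp stranded intervals)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path} line {lineno}: expected >= 6 BED columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, strand = fields[:6]
            intervals.append(
                GenomicInterval(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else ".",
                    name=name,
                    score=float(score) if score not in (".", "") else None,
                )
            )
    return intervals


def centered_windows(
    peaks: Sequence[GenomicInterval],
    size: int = DEFAULT_WINDOW,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Fixed-size windows centered on the midpoint of each peak.

    Windows running past the chromosome start (or past its end when
    `chrom_sizes` is given) are dropped with a logged count.
    """
    if size % 2 != 0:
        raise ValueError("window size must be even")
    half = size // 2
    windows, dropped = [], 0
    for peak in peaks:
        mid = peak.midpoint
        start, end = mid - half, mid + half
        if start < 0 or (
            chrom_sizes is not None
            and peak.chrom in chrom_sizes
            and end > chrom_sizes[peak.chrom]
        ):
            dropped += 1
            continue
        windows.append(
            GenomicInterval(peak.chrom, start, end, peak.strand, peak.name)
        )
    if dropped:
        log.warning("%d windows dropped at chromosome bounds", dropped)
    return windows


def _distance_to_peaks(pos: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Edge-to-point distance from a position to the nearest interval (0 inside)."""
    d = np.maximum.reduce([starts - pos, pos - (ends - 1), np.zeros_like(starts)])
    return int(d.min())


def split_tss_by_proximity(
    tss: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    radius: int = DEFAULT_TSS_RADIUS,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split TSSs into (bound, unbound) windows by peak proximity.

    A TSS is "bound" iff its position lies within `radius` bp of the
    nearest peak interval (distance 0 inside a peak).  Each TSS yields a
    `window` bp interval centered on the TSS with strand preserved; the
    two output lists partition the input.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        sub = [p for p in peaks if p.chrom == chrom]
        by_chrom[chrom] = (
            np.array([p.start for p in sub]),
            np.array([p.end for p in sub]),
        )
    half = window // 2
    bound, unbound = [], []
    for site in tss:
        pos = site.start if site.strand != "-" else site.end - 1
        if site.chrom in by_chrom:
            dist = _distance_to_peaks(pos, *by_chrom[site.chrom])
        else:
            dist = radius + 1
        win_start = pos - half
        if win_start < 0:
            continue
        win = GenomicInterval(
            site.chrom, win_start, pos + (window - half), site.strand, site.name
        )
        (bound if dist <= radius else unbound).append(win)
    return bound, unbound


def extract_sequences(
    windows: Sequence[GenomicInterval],
    genome,
    stranded: bool = False,
    keep_masked_as_n: bool = False,
    role: str = "primary",
) -> SequenceSet:
    """Extract window sequences from an indexed genome FASTA.

    `genome` is a path or an open :class:`pyfaidx.Fasta`.  Windows on a
    missing contig or beyond its bounds are skipped with a logged
    count.  Lowercase (soft-masked) bases become N when
    `keep_masked_as_n` is set, otherwise they are simply uppercased.
    Minus-strand windows are reverse-complemented when `stranded`.
    """
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    records, skipped = [], 0
    expected = {w.end - w.start for w in windows}
    if len(expected) > 1:
        raise ValueError("windows have mixed sizes")
    for i, win in enumerate(windows):
        if win.chrom not in fa:
            skipped += 1
            continue
        contig = fa[win.chrom]
        if win.end > len(contig):
            skipped += 1
            continue
        seq = str(contig[win.start : win.end])
        if keep_masked_as_n:
            seq = "".join("N" if ch.islower() else ch for ch in seq)
        seq = seq.upper()
        if stranded and win.strand == "-":
            seq = seq.translate(_RC)[::-1]
        name = win.name if win.name != "." else f"{win.chrom}:{win.start}-{win.end}"
        if any(rid == name for rid, _ in records):
            name = f"{name}.{i}"
        records.append((name, seq))
    if skipped:
        log.warning("%d windows skipped (missing contig or out of bounds)", skipped)
    if not records:
        raise ValueError("no windows could be extracted")
    return SequenceSet(records, role=role)
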