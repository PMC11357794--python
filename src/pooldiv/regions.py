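"""Genomic region lists and position masks.

Regions subset the variant stream (positions outside are dropped entirely);
masks mark positions invalid while keeping them in the stream so that
window-averaging denominators can still count them.  All coordinates are
stored 1-based inclusive internally; BED input (0-based half-open) is
converted on read.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from intervaltree import IntervalTree


def open_text(path, mode: str = "rt"):
    """Open a text file, transparently handling gzip by magic bytes."""
    if hasattr(path, "read"):
        return path
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class RegionList:
    """A set of (chromosome, start, end) intervals, 1-based inclusive."""

    provenance: str = "text"
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chromosome: str, start: int, end: int) -> None:
        if start > end:
            raise ValueError(f"region start {start} > end {end} on {chromosome}")
        if start < 1:
            raise ValueError(f"region start must be >= 1, got {start}")
        # intervaltree uses half-open [begin, end); store end+1
        self._trees.setdefault(chromosome, IntervalTree()).addi(start, end + 1)

    def __contains__(self, locus: tuple[str, int]) -> bool:
        chrom, pos = locus
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def intervals(self) -> Iterable[tuple[str, int, int]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end - 1

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]],
                       provenance: str = "text") -> "RegionList":
        rl = cls(provenance=provenance)
        for chrom, start, end in intervals:
            rl.add(chrom, start, end)
        return rl


def read_regions(path, fmt: str = "auto") -> RegionList:
    """Read a region list from BED, GFF2/GFF3/GTF, or simple text.

    BED is 0-based half-open, GFF/GTF is 1-based inclusive; simple text
    accepts ``chrom``, ``chrom:pos`` and ``chrom:start-end`` (1-based
    inclusive, whole chromosome encoded as 1..2^31).
    """
    name = getattr(path, "name", str(path)).lower()
    if fmt == "auto":
        stripped = name.removesuffix(".gz")
        if stripped.endswith(".bed"):
            fmt = "bed"
        elif stripped.endswith((".gff", ".gff3", ".gff2", ".gtf")):
            fmt = "gff"
        else:
            fmt = "text"
    if fmt not in ("bed", "gff", "text"):
        raise ValueError(f"unknown region format: {fmt}")
    rl = RegionList(provenance=fmt)
    fh = open_text(path)
    with fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            try:
                if fmt == "bed":
                    parts = line.split("\t")
                    if len(parts) < 3:
                        parts = line.split()
                    chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                    rl.add(chrom, start0 + 1, end0)
                elif fmt == "gff":
                    parts = line.split("\t")
                    chrom, start, end = parts[0], int(parts[3]), int(parts[4])
                    rl.add(chrom, start, end)
                else:
                    _add_text_region(rl, line)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{name}:{lineno}: bad region line: {exc}") from exc
    return rl


_WHOLE_CHROM_END = 2**31 - 1


def _add_text_region(rl: RegionList, token: str) -> None:
    if ":" not in token:
        rl.add(token, 1, _WHOLE_CHROM_END)
        return
    chrom, span = token.rsplit(":", 1)
    if "-" in span:
        start_s, end_s = span.split("-", 1)
        rl.add(chrom, int(start_s), int(end_s))
    else:
        pos = int(span)
        rl.add(chrom, pos, pos)


@dataclass
class Mask:
    """Per-chromosome validity marks; positions absent from the mask are invalid.

    ``scope`` records whether the mask applies to all samples (``global``)
    or to a single sample column.  A chromosome missing from the mask has all
    its positions invalid.
    """

    scope: str = "global"
    _valid: dict[str, set[int]] = field(default_factory=dict)

    def add(self, chromosome: str, position: int) -> None:
        self._valid.setdefault(chromosome, set()).add(position)

    def add_range(self, chromosome: str, start: int, end: int) -> None:
        self._valid.setdefault(chromosome, set()).update(range(start, end + 1))

    def is_valid(self, chromosome: str, position: int) -> bool:
        return position in self._valid.get(chromosome, ())

    @classmethod
    def from_regions(cls, regions: RegionList, scope: str = "global") -> "Mask":
        m = cls(scope=scope)
        for chrom, start, end in regions.intervals():
            m.add_range(chrom, start, min(end, start + 10**7))
        return m

    @classmethod
    def from_file(cls, path, fmt: str = "auto", scope: str = "global") -> "Mask":
        return cls.from_regions(read_regions(path, fmt), scope=scope)
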