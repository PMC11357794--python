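"""Parsers and writers for Pool-seq text formats.

Supported inputs are the PoPoolation2 sync format (per-sample allele counts
``A:T:C:G:N:DEL``), samtools (m)pileup, and simple delimited tables of
allele counts or frequencies.  Multiple sorted input streams can be merged
positionally (union or intersection) into one multi-sample stream.  All
inputs may be gzip-compressed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import BASES, FilterReason, SampleCounts, Variant
from .regions import open_text

# sync on-disk column order differs from the internal A/C/G/T order
_SYNC_ORDER = ("A", "T", "C", "G", "N", "DEL")
_ATTR_OF = {"A": "a_count", "T": "t_count", "C": "c_count", "G": "g_count",
            "N": "n_count", "DEL": "del_count"}


class ParseError(ValueError):
    """A malformed input line; message carries file position context."""


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def parse_sync_line(line: str, lineno: int = 0) -> Variant:
    """Parse one sync line into a :class:`Variant`.

    Columns: chromosome, position, reference base, then one ``A:T:C:G:N:DEL``
    count field per sample.  The 4-field dialect (no N/DEL) is accepted with
    N = DEL = 0.  A sample field of ``.:.:.:.:.:.`` or ``-`` denotes missing
    data and yields an all-zero tally marked filtered.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise ParseError(f"line {lineno}: expected >= 4 tab-separated columns, "
                         f"got {len(fields)}")
    chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer position {pos_s!r}") from exc
    if pos < 1:
        raise ParseError(f"line {lineno}: position must be >= 1, got {pos}")
    samples = []
    for col in fields[3:]:
        if col == "-" or (col and set(col) <= {".", ":"}):
            samples.append(SampleCounts(passed=False, filter_reason=FilterReason.MISSING))
            continue
        tokens = col.split(":")
        if len(tokens) not in (4, 6):
            raise ParseError(f"line {lineno}: sample field {col!r} must have "
                             f"4 or 6 ':'-separated counts")
        sc = SampleCounts()
        try:
            for name, tok in zip(_SYNC_ORDER, tokens):
                setattr(sc, _ATTR_OF[name], int(tok))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer count in {col!r}") from exc
        samples.append(sc)
    if ref not in ("A", "C", "G", "T", "N"):
        ref = "N"
    return Variant(chromosome=chrom, position=pos, ref_base=ref, samples=samples)


def read_sync(path) -> Iterator[Variant]:
    """Stream variants from a sync file; an optional ``#`` header is skipped."""
    fh = open_text(path)
    with fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            yield parse_sync_line(line, lineno)


def format_sync_line(variant: Variant) -> str:
    cols = [variant.chromosome, str(variant.position), variant.ref_base]
    for s in variant.samples:
        if not s.passed and s.filter_reason is FilterReason.MISSING and s.read_depth == 0 \
                and s.n_count == 0 and s.del_count == 0:
            cols.append(".:.:.:.:.:.")
        else:
            cols.append(":".join(str(getattr(s, _ATTR_OF[b])) for b in _SYNC_ORDER))
    return "\t".join(cols)


def write_sync(stream: Iterable[Variant], out) -> int:
    """Write a sorted variant stream as sync lines; returns lines written.

    Raises ``ValueError`` on unsorted input.  ``write_sync`` composed with
    :func:`parse_sync_line` is the identity on well-formed 6-field lines.
    """
    n = 0
    last: Optional[tuple[str, int]] = None
    chrom_rank: dict[str, int] = {}
    for v in stream:
        chrom_rank.setdefault(v.chromosome, len(chrom_rank))
        key = (chrom_rank[v.chromosome], v.position)
        if last is not None and key <= last:
            raise ValueError(f"unsorted stream at {v.chromosome}:{v.position}")
        last = key
        out.write(format_sync_line(v) + "\n")
        n += 1
    return n


# ---------------------------------------------------------------------------
# mpileup
# ---------------------------------------------------------------------------

def _decode_pileup_sample(ref: str, bases: str, quals: str,
                          min_base_quality: int, quality_offset: int,
                          lineno: int) -> SampleCounts:
    """Walk the pileup base-string grammar, pairing count-bearing columns
    with their quality characters."""
    sc = SampleCounts()
    i = 0
    qi = 0

    def next_qual() -> int:
        nonlocal qi
        if qi >= len(quals):
            raise ParseError(f"line {lineno}: base/quality string length mismatch")
        q = ord(quals[qi]) - quality_offset
        qi += 1
        return q

    while i < len(bases):
        ch = bases[i]
        if ch == "^":
            i += 2  # read start: skip caret and mapping-quality char
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            j = i + 1
            num = ""
            while j < len(bases) and bases[j].isdigit():
                num += bases[j]
                j += 1
            if not num:
                raise ParseError(f"line {lineno}: malformed indel at column {i}")
            i = j + int(num)
            continue
        q = next_qual()
        if ch in ".,":
            if q >= min_base_quality and ref in _ATTR_OF and ref != "N":
                setattr(sc, _ATTR_OF[ref], getattr(sc, _ATTR_OF[ref]) + 1)
            elif q >= min_base_quality:
                sc.n_count += 1
        elif ch.upper() in ("A", "C", "G", "T"):
            if q >= min_base_quality:
                b = ch.upper()
                setattr(sc, _ATTR_OF[b], getattr(sc, _ATTR_OF[b]) + 1)
        elif ch == "*":
            if q >= min_base_quality:
                sc.del_count += 1
        elif ch in "><":
            if q >= min_base_quality:
                sc.n_count += 1
        else:  # N or n or anything unrecognised → "any base"
            if q >= min_base_quality:
                sc.n_count += 1
        i += 1
    if qi != len(quals):
        raise ParseError(f"line {lineno}: base/quality string length mismatch")
    return sc


def parse_mpileup_line(line: str, min_base_quality: int = 0,
                       quality_offset: int = 33, lineno: int = 0) -> Variant:
    """Parse one samtools (m)pileup line.

    Per sample there are three columns (depth, base string, quality string).
    ``.``/``,`` map to the reference base, letters to their base, ``*`` to
    the deletion tally and ``>``/``<`` to the "any base" tally; a column is
    only counted when its quality character decodes to at least
    ``min_base_quality`` (Sanger offset 33 by default).
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6 or (len(fields) - 3) % 3 != 0:
        raise ParseError(f"line {lineno}: expected 3 + 3*k pileup columns, "
                         f"got {len(fields)}")
    chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer position {pos_s!r}") from exc
    if pos < 1:
        raise ParseError(f"line {lineno}: position must be >= 1, got {pos}")
    samples = []
    for k in range(3, len(fields), 3):
        depth_s, bases, quals = fields[k], fields[k + 1], fields[k + 2]
        if depth_s == "0" and bases in ("*", ""):
            samples.append(SampleCounts(passed=False, filter_reason=FilterReason.MISSING))
            continue
        samples.append(_decode_pileup_sample(ref, bases, quals, min_base_quality,
                                             quality_offset, lineno))
    if ref not in ("A", "C", "G", "T", "N"):
        ref = "N"
    return Variant(chromosome=chrom, position=pos, ref_base=ref, samples=samples)


def read_mpileup(path, min_base_quality: int = 0, quality_offset: int = 33
                 ) -> Iterator[Variant]:
    fh = open_text(path)
    with fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            yield parse_mpileup_line(line, min_base_quality, quality_offset, lineno)


# ---------------------------------------------------------------------------
# frequency / count tables
# ---------------------------------------------------------------------------

@dataclass
class TableSchema:
    """Column layout of a simple delimited allele table.

    ``kind='frequency'`` expects one column per sample holding the alt-allele
    frequency in [0, 1], converted to pseudo-counts at ``scaling_depth``
    (useful for haplotype-corrected frequencies where the read-depth
    correction is less relevant but the pool-size correction still applies).
    ``kind='counts'`` expects ``<sample>_ref`` and ``<sample>_alt`` columns
    passed through unchanged.
    """

    samples: Sequence[str]
    kind: str = "frequency"
    chrom_col: str = "chrom"
    pos_col: str = "pos"
    ref_col: str = "ref"
    alt_col: str = "alt"
    scaling_depth: int = 100
    sep: str = "\t"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def read_frequency_table(path, schema: TableSchema) -> Iterator[Variant]:
    """Stream variants from a delimited table of per-sample counts/frequencies."""
    df = pd.read_csv(path, sep=schema.sep)
    required = [schema.chrom_col, schema.pos_col, schema.ref_col, schema.alt_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"table missing required columns: {missing}")
    for _, row in df.iterrows():
        ref = str(row[schema.ref_col]).upper()
        alt = str(row[schema.alt_col]).upper()
        samples = []
        for s in schema.samples:
            if schema.kind == "frequency":
                f = float(row[s])
                if not 0.0 <= f <= 1.0:
                    raise ParseError(f"frequency {f} outside [0, 1] for sample {s}")
                n0 = schema.scaling_depth
                ref_n = _round_half_away((1.0 - f) * n0)
                alt_n = _round_half_away(f * n0)
            else:
                ref_n = int(row[f"{s}_ref"])
                alt_n = int(row[f"{s}_alt"])
            sc = SampleCounts.from_bases(**{ref: ref_n})
            if alt in _ATTR_OF and alt != ref:
                setattr(sc, _ATTR_OF[alt], alt_n)
            samples.append(sc)
        yield Variant(chromosome=str(row[schema.chrom_col]),
                      position=int(row[schema.pos_col]),
                      ref_base=ref if ref in "ACGTN" else "N",
                      alt_base=alt if alt in "ACGTN" else "N",
                      samples=samples)


# ---------------------------------------------------------------------------
# reference genomes
# ---------------------------------------------------------------------------

def read_reference(path) -> dict[str, str]:
    """Load a FASTA reference genome into a chromosome -> sequence mapping."""
    from Bio import SeqIO
    fh = open_text(path)
    with fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# multi-file traversal
# ---------------------------------------------------------------------------

def merge_streams(streams: Sequence[Iterable[Variant]], mode: str = "union",
                  reference: Optional[Mapping[str, str]] = None,
                  chromosome_order: Optional[Sequence[str]] = None,
                  sample_counts: Optional[Sequence[int]] = None,
                  ) -> Iterator[Variant]:
    """Traverse several sorted variant streams positionally as one stream.

    Output has one variant per position present in the union (absent samples
    filled with missing tallies) or intersection of the inputs, with sample
    columns concatenated in input order.  Reference-base conflicts are
    resolved with priority reference genome > first non-N input; conflicting
    non-N bases without a reference genome raise an error naming the position.
    Chromosomes follow ``chromosome_order`` when given, else lexicographic.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    iters = [iter(s) for s in streams]
    heads: list[Optional[Variant]] = [next(it, None) for it in iters]
    n_samples = list(sample_counts) if sample_counts else [
        len(h.samples) if h is not None else 1 for h in heads]
    rank: dict[str, int] = {}
    if chromosome_order is not None:
        rank = {c: i for i, c in enumerate(chromosome_order)}

    def key(v: Variant) -> tuple:
        if chromosome_order is not None:
            if v.chromosome not in rank:
                raise ValueError(f"chromosome {v.chromosome} not in chromosome order")
            return (rank[v.chromosome], v.position)
        return (v.chromosome, v.position)

    last_keys: list[Optional[tuple]] = [None] * len(iters)
    while any(h is not None for h in heads):
        cur = min(key(h) for h in heads if h is not None)
        present = [i for i, h in enumerate(heads) if h is not None and key(h) == cur]
        chrom = heads[present[0]].chromosome
        pos = heads[present[0]].position
        if mode == "union" or len(present) == len(iters):
            samples: list[SampleCounts] = []
            ref = "N"
            ref_src = -1
            for i, h in enumerate(heads):
                if i in present:
                    samples.extend(h.samples)
                    if h.ref_base not in ("N", ""):
                        if ref == "N":
                            ref, ref_src = h.ref_base, i
                        elif h.ref_base != ref and reference is None:
                            raise ValueError(
                                f"conflicting reference bases at {chrom}:{pos} "
                                f"(streams {ref_src} and {i}: {ref} vs {h.ref_base})")
                else:
                    samples.extend(SampleCounts(passed=False,
                                                filter_reason=FilterReason.MISSING)
                                   for _ in range(n_samples[i]))
            if reference is not None:
                seq = reference.get(chrom)
                if seq is not None and 1 <= pos <= len(seq) and seq[pos - 1] in "ACGT":
                    ref = seq[pos - 1]
            yield Variant(chromosome=chrom, position=pos, ref_base=ref, samples=samples)
        for i in present:
            nxt = next(iters[i], None)
            if nxt is not None:
                k = key(nxt)
                if last_keys[i] is not None and k <= last_keys[i] or k <= cur:
                    raise ValueError(f"stream {i} not sorted at "
                                     f"{nxt.chromosome}:{nxt.position}")
                last_keys[i] = k
            heads[i] = nxt
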