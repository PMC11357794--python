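"""Assemble a filtered variant stream into genomic windows and compute the
per-window averaging denominators.

Six window types are supported: fixed-size intervals (optionally sliding,
with a stride smaller than the width), a fixed number of SNPs per window,
user-defined regions (possibly nested/overlapping), single SNPs, whole
chromosomes, and the whole genome.  Windows carry bookkeeping tallies so
that per-window sums can be turned into per-base-pair averages under six
denominator policies: window size, available loci (positions with data),
valid loci (positions that passed all filters; the recommended default),
SNP count, no averaging (report the sum), or a user-supplied mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence

from .filters import SiteClass, classify_site
from .model import Variant
from .regions import Mask, RegionList

POLICIES = ("window-size", "available-loci", "valid-loci", "snp-count", "sum", "mask")


@dataclass
class WindowConfig:
    """How the stream is cut into windows."""

    type: str = "interval"  # interval | snp_count | regions | single_snp | chromosome | genome
    width: int = 1000
    stride: int = 0  # 0 = width (non-overlapping)
    count: int = 100  # SNPs per window for snp_count
    regions: Optional[RegionList] = None

    def __post_init__(self) -> None:
        if self.type not in ("interval", "snp_count", "regions", "single_snp",
                             "chromosome", "genome"):
            raise ValueError(f"unknown window type: {self.type!r}")
        if self.width < 1 or self.count < 1:
            raise ValueError("window width and SNP count must be >= 1")
        if self.stride == 0:
            self.stride = self.width
        if not 1 <= self.stride <= self.width:
            raise ValueError("stride must satisfy 1 <= stride <= width")
        if self.type == "regions" and self.regions is None:
            raise ValueError("regions window type requires a region list")


@dataclass
class Window:
    """A labeled stretch of the genome with its assigned variants and tallies."""

    chromosome: str
    first: int
    last: int
    entries: list[Variant] = field(default_factory=list)
    n_with_data: int = 0
    n_passed: int = 0
    n_passed_mask_valid: int = 0
    n_snps: int = 0
    passed_by_sample: list[int] = field(default_factory=list)
    snps_by_sample: list[int] = field(default_factory=list)
    acc: object = None  # optional streaming statistics accumulator

    @property
    def size(self) -> int:
        return self.last - self.first + 1

    def add(self, variant: Variant, site_class: Optional[SiteClass] = None,
            mask: Optional[Mask] = None, store: bool = True) -> None:
        if site_class is None:
            site_class = _site_class(variant)
        self.n_with_data += 1
        if not self.passed_by_sample:
            self.passed_by_sample = [0] * len(variant.samples)
            self.snps_by_sample = [0] * len(variant.samples)
        if variant.passed:
            self.n_passed += 1
            if mask is None or mask.is_valid(variant.chromosome, variant.position):
                self.n_passed_mask_valid += 1
            if site_class.is_snp:
                self.n_snps += 1
            for i, s in enumerate(variant.samples):
                if s.passed:
                    self.passed_by_sample[i] += 1
                    if sum(1 for c in s.base_counts() if c > 0) >= 2:
                        self.snps_by_sample[i] += 1
        if store:
            self.entries.append(variant)
        if self.acc is not None:
            self.acc.add(variant, site_class)


def _site_class(v: Variant) -> SiteClass:
    cls = getattr(v, "site_class", None)
    return cls if cls is not None else classify_site(v)


def make_windows(stream: Iterable[Variant], cfg: WindowConfig,
                 chromosome_lengths: Optional[dict[str, int]] = None,
                 mask: Optional[Mask] = None,
                 accumulator_factory: Optional[Callable[[], object]] = None,
                 store_entries: Optional[bool] = None) -> Iterator[Window]:
    """Cut a sorted variant stream into windows.

    Interval, SNP-count and region windows buffer at most the variants of
    the currently open windows; single-SNP, chromosome and genome windows
    stream with constant per-position memory when ``store_entries`` is off
    (the default for those types when an accumulator is supplied).
    """
    if store_entries is None:
        store_entries = not (accumulator_factory is not None and
                             cfg.type in ("single_snp", "chromosome", "genome"))

    def new_window(chrom: str, first: int, last: int) -> Window:
        w = Window(chromosome=chrom, first=first, last=last)
        if accumulator_factory is not None:
            w.acc = accumulator_factory()
        return w

    if cfg.type == "interval":
        yield from _interval_windows(stream, cfg, chromosome_lengths, mask,
                                     new_window, store_entries)
    elif cfg.type == "snp_count":
        yield from _snp_count_windows(stream, cfg, mask, new_window, store_entries)
    elif cfg.type == "regions":
        yield from _region_windows(stream, cfg, mask, new_window, store_entries)
    elif cfg.type == "single_snp":
        for v in stream:
            cls = _site_class(v)
            if v.passed and cls.is_snp:
                w = new_window(v.chromosome, v.position, v.position)
                w.add(v, cls, mask, store_entries)
                yield w
    elif cfg.type == "chromosome":
        cur: Optional[Window] = None
        for v in stream:
            if cur is None or v.chromosome != cur.chromosome:
                if cur is not None:
                    yield _finalize_chrom(cur, chromosome_lengths)
                cur = new_window(v.chromosome, 1, v.position)
            cur.last = max(cur.last, v.position)
            cur.add(v, _site_class(v), mask, store_entries)
        if cur is not None:
            yield _finalize_chrom(cur, chromosome_lengths)
    elif cfg.type == "genome":
        w = new_window("genome", 1, 1)
        span = 0
        last_chrom = None
        last_pos = 0
        for v in stream:
            if v.chromosome != last_chrom:
                span += last_pos if chromosome_lengths is None else 0
                last_chrom, last_pos = v.chromosome, 0
            last_pos = max(last_pos, v.position)
            w.add(v, _site_class(v), mask, store_entries)
        if chromosome_lengths:
            w.last = sum(chromosome_lengths.values())
        else:
            w.last = max(1, span + last_pos)
        yield w


def _finalize_chrom(w: Window, lengths: Optional[dict[str, int]]) -> Window:
    if lengths and w.chromosome in lengths:
        w.last = lengths[w.chromosome]
    return w


def _interval_windows(stream, cfg, lengths, mask, new_window, store):
    width, stride = cfg.width, cfg.stride
    open_ws: dict[int, Window] = {}  # window index -> Window
    chrom: Optional[str] = None
    max_idx_emitted = -1

    def bounds(chrom_: str, idx: int) -> tuple[int, int]:
        first = idx * stride + 1
        last = first + width - 1
        if lengths and chrom_ in lengths:
            last = min(last, lengths[chrom_])
        return first, last

    def flush(chrom_: str, upto_idx: Optional[int], last_seen: int):
        # emit (in order) all windows with index < upto_idx, or all if None
        nonlocal max_idx_emitted
        final = upto_idx is None
        idxs = sorted(open_ws)
        for idx in idxs:
            if upto_idx is not None and idx >= upto_idx:
                break
            w = open_ws.pop(idx)
            # only the trailing window(s) are truncated, and only when the
            # chromosome length is unknown
            if final and (lengths is None or chrom_ not in lengths):
                w.last = min(w.last, max(last_seen, w.first))
            yield w
            max_idx_emitted = idx
        if upto_idx is None:
            # trailing windows up to chromosome length, if known
            if lengths and chrom_ in lengths:
                n_windows = _n_interval_windows(lengths[chrom_], width, stride)
                for idx in range(max_idx_emitted + 1, n_windows):
                    if idx in open_ws:
                        yield open_ws.pop(idx)
                    else:
                        yield new_window(chrom_, *bounds(chrom_, idx))

    last_seen = 0
    for v in stream:
        if chrom is not None and v.chromosome != chrom:
            yield from flush(chrom, None, last_seen)
            open_ws.clear()
            max_idx_emitted = -1
        chrom = v.chromosome
        pos = v.position
        lo = max(0, -(-(pos - width) // stride))  # ceil((pos-width)/stride)
        hi = (pos - 1) // stride
        # open any not-yet-seen windows (including empty gap windows) so the
        # output covers the observed range, then emit those now fully behind
        start_idx = max(open_ws) + 1 if open_ws else max_idx_emitted + 1
        for idx in range(start_idx, hi + 1):
            open_ws[idx] = new_window(chrom, *bounds(chrom, idx))
        yield from flush(chrom, lo, last_seen)
        for idx in range(lo, hi + 1):
            open_ws[idx].add(v, _site_class(v), mask, store)
        last_seen = pos
    if chrom is not None:
        yield from flush(chrom, None, last_seen)


def _n_interval_windows(length: int, width: int, stride: int) -> int:
    if length <= width:
        return 1
    return -(-(length - width) // stride) + 1


def _snp_count_windows(stream, cfg, mask, new_window, store):
    # non-SNP positions are buffered and only join a window once a later SNP
    # extends its bounds past them; positions between windows are unassigned
    cur: Optional[Window] = None
    pending: list = []
    chrom: Optional[str] = None
    for v in stream:
        if chrom is not None and v.chromosome != chrom:
            if cur is not None:
                yield cur
                cur = None
            pending.clear()
        chrom = v.chromosome
        cls = _site_class(v)
        is_snp = v.passed and cls.is_snp
        if not is_snp:
            if cur is not None:
                pending.append((v, cls))
            continue
        if cur is None:
            pending.clear()  # positions before the window's first SNP
            cur = new_window(chrom, v.position, v.position)
        cur.last = v.position
        for pv, pcls in pending:
            cur.add(pv, pcls, mask, store)
        pending.clear()
        cur.add(v, cls, mask, store)
        if cur.n_snps >= cfg.count:
            yield cur
            cur = None
            pending.clear()
    if cur is not None:
        yield cur


def _region_windows(stream, cfg, mask, new_window, store):
    pending: dict[tuple[str, int, int], Window] = {
        (c, s, e): None for c, s, e in cfg.regions.intervals()}  # insertion order
    open_ws: dict[tuple[str, int, int], Window] = {}
    chrom = None
    for v in stream:
        if chrom is not None and v.chromosome != chrom:
            for key in [k for k in open_ws if k[0] == chrom]:
                yield open_ws.pop(key)
        chrom = v.chromosome
        # close windows that end before this position
        for key in sorted(k for k in open_ws if k[0] == chrom and k[2] < v.position):
            yield open_ws.pop(key)
        for key in list(pending):
            c, s, e = key
            if c == chrom and s <= v.position <= e:
                open_ws[key] = new_window(c, s, e)
                del pending[key]
        for (c, s, e), w in open_ws.items():
            if c == chrom and s <= v.position <= e:
                w.add(v, _site_class(v), mask, store)
    for key in sorted(open_ws):
        yield open_ws[key]


def window_denominator(window: Window, policy: str,
                       mask: Optional[Mask] = None,
                       sample_index: Optional[int] = None) -> Optional[float]:
    """The averaging denominator of a window under one of the six policies.

    Returns ``None`` (not-available) instead of a zero denominator so
    callers never divide by zero.  With ``sample_index`` given, the
    valid-loci and snp-count policies use that sample's own tallies.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown averaging policy: {policy!r} (one of {POLICIES})")
    if policy == "window-size":
        d = window.size
    elif policy == "available-loci":
        d = window.n_with_data
    elif policy == "valid-loci":
        if sample_index is not None and window.passed_by_sample:
            d = window.passed_by_sample[sample_index]
        elif mask is not None:
            d = window.n_passed_mask_valid
        else:
            d = window.n_passed
    elif policy == "snp-count":
        if sample_index is not None and window.snps_by_sample:
            d = window.snps_by_sample[sample_index]
        else:
            d = window.n_snps
    elif policy == "sum":
        d = 1
    else:  # mask
        if mask is None:
            raise ValueError("mask policy requires a mask")
        d = _mask_valid_in_bounds(window, mask)
    return float(d) if d > 0 else None


def _mask_valid_in_bounds(window: Window, mask: Mask) -> int:
    valid = mask._valid
    if window.chromosome == "genome":
        return sum(len(s) for s in valid.values())
    positions = valid.get(window.chromosome, ())
    return sum(1 for p in positions if window.first <= p <= window.last)
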