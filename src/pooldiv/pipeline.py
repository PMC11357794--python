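"""High-level runs: wire inputs → filters → windows → estimators → tables.

These functions are the library equivalents of the command-line subcommands:
they read one or more Pool-seq inputs, push them through the filter cascade
and the windowing layer, compute diversity or F_ST per window, and write a
tab-separated table with one row per window plus a run-summary tally of the
cascade (positions read / removed / passed / SNPs).  Output is deterministic
given a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Optional, Sequence

from .diversity import DiversityAccumulator
from .filters import FilterCascade, SampleFilterConfig
from .formats import (TableSchema, merge_streams, read_frequency_table,
                      read_mpileup, read_reference, read_sync, write_sync)
from .fst import FST_METHODS, FstAccumulator
from .model import PoolProfile, Variant, check_sorted, infer_ref_alt
from .regions import Mask, RegionList, read_regions
from .windows import Window, WindowConfig, make_windows

log = logging.getLogger("pooldiv")

NA = "nan"


@dataclass
class InputSpec:
    """One input file with its format and idiosyncratic options."""

    path: str
    format: str = "sync"  # sync | mpileup | table
    min_base_quality: int = 0
    quality_offset: int = 33
    table_schema: Optional[TableSchema] = None

    def open(self) -> Iterator[Variant]:
        if self.format == "sync":
            return read_sync(self.path)
        if self.format == "mpileup":
            return read_mpileup(self.path, self.min_base_quality, self.quality_offset)
        if self.format == "table":
            if self.table_schema is None:
                raise ValueError("table input requires a TableSchema")
            return read_frequency_table(self.path, self.table_schema)
        raise ValueError(f"unknown input format: {self.format!r}")


@dataclass
class RunConfig:
    """Everything one run needs; the CLI is a thin flag-to-field mapping."""

    inputs: list[InputSpec] = field(default_factory=list)
    multi_file_mode: str = "union"
    chromosome_order: Optional[Sequence[str]] = None
    reference_path: Optional[str] = None
    pool_sizes: Sequence[int] = ()
    min_count: int = 2
    filters: SampleFilterConfig = field(default_factory=SampleFilterConfig)
    regions: Optional[RegionList] = None
    invert_regions: bool = False
    mask: Optional[Mask] = None
    subsample_max_depth: int = 0
    subsample_method: str = "rescale"
    window: WindowConfig = field(default_factory=WindowConfig)
    window_policy: str = "valid-loci"
    window_mask: Optional[Mask] = None
    chromosome_lengths: Optional[dict[str, int]] = None
    fst_method: str = "hudson"
    fst_pairs: Optional[Sequence[tuple[int, int]]] = None
    emit_pi_parts: bool = False
    normalize_tajimas_d: bool = False
    seed: int = 0
    output: str = "-"

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input is required")
        if self.fst_method not in FST_METHODS:
            raise ValueError(f"unknown F_ST method {self.fst_method!r}")


def _prepared_stream(cfg: RunConfig) -> tuple[Iterator[Variant], FilterCascade]:
    reference = read_reference(cfg.reference_path) if cfg.reference_path else None
    streams = [spec.open() for spec in cfg.inputs]
    if len(streams) == 1:
        stream: Iterable[Variant] = check_sorted(streams[0], cfg.chromosome_order)
    else:
        stream = merge_streams(streams, mode=cfg.multi_file_mode,
                               reference=reference,
                               chromosome_order=cfg.chromosome_order)
    cascade = FilterCascade(
        regions=cfg.regions, invert_regions=cfg.invert_regions, mask=cfg.mask,
        sample_cfg=cfg.filters, subsample_max_depth=cfg.subsample_max_depth,
        subsample_method=cfg.subsample_method, seed=cfg.seed)

    def annotate(vs: Iterable[Variant]) -> Iterator[Variant]:
        # a declared ref base from the input is kept; a reference genome
        # overrides; only missing bases are inferred from the counts
        for v in vs:
            if reference is not None or v.ref_base not in "ACGT":
                v.ref_base, v.alt_base = infer_ref_alt(v, reference)
            elif v.alt_base not in "ACGT":
                counts = v.merged_counts(passed_only=False).base_counts()
                order = sorted(range(4), key=lambda i: (-counts[i], i))
                v.alt_base = next((("A", "C", "G", "T")[i] for i in order
                                   if ("A", "C", "G", "T")[i] != v.ref_base
                                   and counts[i] > 0), "N")
            yield v

    return cascade(annotate(stream)), cascade


def _pool_profile(cfg: RunConfig, n_samples: int) -> PoolProfile:
    sizes = list(cfg.pool_sizes)
    if len(sizes) == 1 and n_samples > 1:
        sizes = sizes * n_samples
    if len(sizes) != n_samples:
        raise ValueError(f"{n_samples} samples but {len(sizes)} pool sizes given")
    return PoolProfile(pool_sizes=tuple(sizes), min_count=cfg.min_count)


def _fmt(x) -> str:
    return NA if x is None else f"{x:.10g}"


def _open_out(path: str):
    import sys
    if path == "-":
        return sys.stdout
    return open(path, "w")


def run_diversity(cfg: RunConfig) -> dict:
    """Per-window diversity table; returns the run-summary tally."""
    stream, cascade = _prepared_stream(cfg)
    stream = iter(stream)
    first = next(stream, None)
    if first is None:
        out = _open_out(cfg.output)
        out.write("chrom\tstart\tend\n")
        if cfg.output != "-":
            out.close()
        log.warning("empty input: no data rows written")
        return cascade.tally.as_dict()
    n_samples = len(first.samples)
    pools = _pool_profile(cfg, n_samples)

    def chained():
        yield first
        yield from stream

    out = _open_out(cfg.output)
    cols = ["chrom", "start", "end"]
    for i in range(n_samples):
        cols += [f"s{i}.theta_pi_abs", f"s{i}.theta_pi_rel",
                 f"s{i}.theta_w_abs", f"s{i}.theta_w_rel",
                 f"s{i}.tajimas_d", f"s{i}.passed", f"s{i}.snps"]
    out.write("\t".join(cols) + "\n")
    windows = make_windows(chained(), cfg.window, cfg.chromosome_lengths,
                           mask=cfg.window_mask,
                           accumulator_factory=lambda: DiversityAccumulator(pools),
                           store_entries=False)
    n_windows = 0
    for w in windows:
        acc: DiversityAccumulator = w.acc
        row = [w.chromosome, str(w.first), str(w.last)]
        for r in acc.results(w, policy=cfg.window_policy, mask=cfg.window_mask,
                             normalize_d=cfg.normalize_tajimas_d):
            row += [_fmt(r.theta_pi_sum), _fmt(r.theta_pi),
                    _fmt(r.theta_w_sum), _fmt(r.theta_w),
                    _fmt(r.tajimas_d), str(r.n_passed), str(r.n_snps)]
        out.write("\t".join(row) + "\n")
        n_windows += 1
    if cfg.output != "-":
        out.close()
    tally = cascade.tally.as_dict()
    tally["windows"] = n_windows
    log.info("diversity run: %s", tally)
    return tally


def run_fst(cfg: RunConfig) -> dict:
    """Per-window pairwise F_ST table; returns the run-summary tally."""
    stream, cascade = _prepared_stream(cfg)
    stream = iter(stream)
    first = next(stream, None)
    if first is None:
        out = _open_out(cfg.output)
        out.write("chrom\tstart\tend\n")
        if cfg.output != "-":
            out.close()
        log.warning("empty input: no data rows written")
        return cascade.tally.as_dict()
    n_samples = len(first.samples)
    if n_samples < 2:
        raise ValueError("F_ST requires at least 2 samples")
    pools = _pool_profile(cfg, n_samples)
    pairs = list(cfg.fst_pairs) if cfg.fst_pairs else list(combinations(range(n_samples), 2))

    def chained():
        yield first
        yield from stream

    out = _open_out(cfg.output)
    cols = ["chrom", "start", "end"]
    for i, j in pairs:
        cols.append(f"s{i}:s{j}.fst_{cfg.fst_method}")
        if cfg.emit_pi_parts:
            cols += [f"s{i}:s{j}.pi_within", f"s{i}:s{j}.pi_between",
                     f"s{i}:s{j}.pi_total"]
    out.write("\t".join(cols) + "\n")
    windows = make_windows(chained(), cfg.window, cfg.chromosome_lengths,
                           mask=cfg.window_mask,
                           accumulator_factory=lambda: FstAccumulator(pools, pairs),
                           store_entries=False)
    n_windows = 0
    for w in windows:
        acc: FstAccumulator = w.acc
        values = acc.results(cfg.fst_method)
        row = [w.chromosome, str(w.first), str(w.last)]
        for pair in pairs:
            row.append(_fmt(values[pair]))
            if cfg.emit_pi_parts:
                part = acc.parts[pair]
                row += [_fmt(part.pi_within_sum), _fmt(part.pi_between_sum),
                        _fmt(part.pi_total_sum)]
        out.write("\t".join(row) + "\n")
        n_windows += 1
    if cfg.output != "-":
        out.close()
    tally = cascade.tally.as_dict()
    tally["windows"] = n_windows
    log.info("fst run: %s", tally)
    return tally


def run_sync_convert(cfg: RunConfig) -> dict:
    """Convert/merge any supported input to sync after the filter cascade."""
    stream, cascade = _prepared_stream(cfg)
    out = _open_out(cfg.output)
    write_sync(stream, out)
    if cfg.output != "-":
        out.close()
    tally = cascade.tally.as_dict()
    log.info("sync run: %s", tally)
    return tally
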