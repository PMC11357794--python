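"""Core per-position data model for pooled sequencing data.

Every input format is normalised into a stream of :class:`Variant` records,
one per genomic position, each holding one :class:`SampleCounts` tally per
sample.  All downstream filters, windows and estimators consume this uniform
representation, so that file-format idiosyncrasies never leak into the
statistics.

Conventions
-----------
* Positions are 1-based and inclusive throughout the package.
* ``N`` ("any base") and ``DEL`` (deletion evidence) tallies are parsed and
  stored, but are excluded from read depth and from all statistics.
* Pool size ``p`` counts *haploid genome copies* in the pool (individuals
  times ploidy), because the estimator denominators sum over the ``p - 1``
  possible derived-allele copy numbers in the pool.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class FilterReason(str, enum.Enum):
    """Why a sample or variant was marked as filtered."""

    MISSING = "missing"
    MASKED = "masked"
    LOW_DEPTH = "low_depth"
    HIGH_DEPTH = "high_depth"
    DELETION = "deletion"
    NOT_SNP = "not_snp"
    NOT_BIALLELIC = "not_biallelic"
    BELOW_MAF = "below_maf"
    REGION = "region"


@dataclass
class SampleCounts:
    """Nucleotide read tallies for one sample at one genomic position.

    ``n_count`` counts reads with an ambiguous base call and ``del_count``
    counts reads supporting a deletion; both are bookkeeping only and never
    contribute to :meth:`read_depth` or to any statistic.
    """

    a_count: int = 0
    c_count: int = 0
    g_count: int = 0
    t_count: int = 0
    n_count: int = 0
    del_count: int = 0
    passed: bool = True
    filter_reason: Optional[FilterReason] = None

    def __post_init__(self) -> None:
        for name in ("a_count", "c_count", "g_count", "t_count", "n_count", "del_count"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def read_depth(self) -> int:
        """Read depth n = A + C + G + T (N and DEL excluded)."""
        return self.a_count + self.c_count + self.g_count + self.t_count

    def base_counts(self) -> tuple[int, int, int, int]:
        """The four nucleotide tallies in fixed A, C, G, T order."""
        return (self.a_count, self.c_count, self.g_count, self.t_count)

    def count_of(self, base: str) -> int:
        return self.base_counts()[_BASE_INDEX[base]]

    def mark_filtered(self, reason: FilterReason) -> None:
        self.passed = False
        self.filter_reason = reason

    def copy(self) -> "SampleCounts":
        return replace(self)

    @classmethod
    def from_bases(cls, **bases: int) -> "SampleCounts":
        """Build from keyword tallies, e.g. ``SampleCounts.from_bases(A=6, C=2)``."""
        mapping = {"A": "a_count", "C": "c_count", "G": "g_count", "T": "t_count",
                   "N": "n_count", "D": "del_count", "DEL": "del_count"}
        kwargs = {mapping[k.upper()]: v for k, v in bases.items()}
        return cls(**kwargs)


def read_depth(counts: SampleCounts) -> int:
    """Read depth of a sample tally: the sum A+C+G+T."""
    return counts.read_depth


def merge_counts(counts_list: Sequence[SampleCounts]) -> SampleCounts:
    """Element-wise sum of sample tallies, e.g. for grouping sequencing runs.

    Filtered members contribute zero; the result is passed iff at least one
    input passed.  Raises ``ValueError`` on an empty list, which indicates an
    invalid sample-grouping configuration.
    """
    if not counts_list:
        raise ValueError("cannot merge an empty list of sample counts")
    out = SampleCounts(passed=False, filter_reason=FilterReason.MISSING)
    for c in counts_list:
        if not c.passed:
            continue
        out.a_count += c.a_count
        out.c_count += c.c_count
        out.g_count += c.g_count
        out.t_count += c.t_count
        out.n_count += c.n_count
        out.del_count += c.del_count
        out.passed = True
        out.filter_reason = None
    return out


@dataclass
class Variant:
    """One genomic position: coordinates, ref/alt bases, per-sample tallies."""

    chromosome: str
    position: int
    ref_base: str = "N"
    alt_base: str = "N"
    samples: list[SampleCounts] = field(default_factory=list)
    passed: bool = True
    filter_reason: Optional[FilterReason] = None

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def merged_counts(self, passed_only: bool = True) -> SampleCounts:
        """Tallies summed over samples (passed samples only by default)."""
        total = SampleCounts(passed=False, filter_reason=FilterReason.MISSING)
        members = [s for s in self.samples if s.passed] if passed_only else self.samples
        if not members:
            return total
        return merge_counts([s if s.passed else replace(s, passed=True) for s in members])

    def mark_filtered(self, reason: FilterReason) -> None:
        self.passed = False
        self.filter_reason = reason


@dataclass(frozen=True)
class PoolProfile:
    """Per-sample pool sizes and the estimator min-count setting.

    ``pool_sizes[i]`` is the number of haploid genome copies in pool *i*
    (first level of sampling noise); ``min_count`` is the smallest per-allele
    read count ``b`` treated as real signal inside the estimator denominators.
    """

    pool_sizes: tuple[int, ...]
    min_count: int = 2

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        for p in self.pool_sizes:
            if p < 2:
                raise ValueError(f"pool size must be >= 2 for estimation, got {p}")

    @classmethod
    def uniform(cls, pool_size: int, n_samples: int, min_count: int = 2) -> "PoolProfile":
        return cls(pool_sizes=(pool_size,) * n_samples, min_count=min_count)


def infer_ref_alt(
    variant: Variant,
    reference: Optional[Mapping[str, str]] = None,
    warn: Optional[list[str]] = None,
) -> tuple[str, str]:
    """Infer reference and alternative base for a variant.

    With a reference genome lookup (mapping chromosome -> sequence string,
    1-based positions), the reference base is taken from it and the
    alternative is the highest-count other base.  Without one, ref and alt
    are the two most common bases across the merged sample tallies.  Ties are
    broken by the fixed base order A < C < G < T so that output is
    deterministic.  Alt is ``N`` when no second base was observed.

    If the reference base disagrees with every observed base, a warning
    message is appended to ``warn`` (if given) and the counts are retained.
    """
    merged = variant.merged_counts(passed_only=False)
    counts = merged.base_counts()
    # sort bases by (count desc, alphabetical) — deterministic tie-break
    order = sorted(range(4), key=lambda i: (-counts[i], BASES[i]))
    ref: Optional[str] = None
    if reference is not None:
        seq = reference.get(variant.chromosome)
        if seq is not None and 1 <= variant.position <= len(seq):
            base = seq[variant.position - 1].upper()
            if base in _BASE_INDEX:
                ref = base
                if counts[_BASE_INDEX[base]] == 0 and merged.read_depth > 0 and warn is not None:
                    warn.append(
                        f"{variant.chromosome}:{variant.position}: reference base "
                        f"{base} not among observed counts"
                    )
    if ref is None:
        ref = BASES[order[0]] if counts[order[0]] > 0 else (
            variant.ref_base if variant.ref_base in _BASE_INDEX else "N")
    alt = "N"
    for i in order:
        if BASES[i] != ref and counts[i] > 0:
            alt = BASES[i]
            break
    return ref, alt


def check_sorted(stream: Iterable[Variant], chromosome_order: Optional[Sequence[str]] = None):
    """Yield variants, raising ``ValueError`` if the stream is not sorted by
    (chromosome, position).  Chromosomes follow ``chromosome_order`` when
    given, otherwise their order of first appearance."""
    seen: dict[str, int] = {}
    if chromosome_order is not None:
        seen = {c: i for i, c in enumerate(chromosome_order)}
    last: Optional[tuple[int, int]] = None
    for v in stream:
        if v.chromosome not in seen:
            seen[v.chromosome] = len(seen)
        key = (seen[v.chromosome], v.position)
        if last is not None and key <= last:
            raise ValueError(
                f"input stream not sorted at {v.chromosome}:{v.position}")
        last = key
        yield v
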