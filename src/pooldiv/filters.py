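"""The filter cascade: regions, masks, numerical filters, SNP detection,
and read-depth subsampling.

The cascade order is fixed: region filters (which remove positions from the
stream entirely) → masks (which mark positions invalid but keep them so
window denominators can count them) → per-sample numerical filters → SNP
classification across samples → optional depth subsampling.  Applying the
cascade twice equals applying it once, given deterministic methods or seed
reuse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .model import BASES, FilterReason, SampleCounts, Variant
from .regions import Mask, RegionList


class SiteClass(enum.Enum):
    """Classification of a site from its post-filter merged base counts."""

    MISSING = "missing"
    INVARIANT = "invariant"
    SNP_BIALLELIC = "snp_biallelic"
    SNP_MULTIALLELIC = "snp_multiallelic"

    @property
    def is_snp(self) -> bool:
        return self in (SiteClass.SNP_BIALLELIC, SiteClass.SNP_MULTIALLELIC)


@dataclass
class SampleFilterConfig:
    """Numerical per-sample filters and across-sample SNP settings.

    ``min_count`` zeroes any base tally strictly below it (rare bases treated
    as sequencing error); depth bounds of 0 mean "off".  ``min_allele_frequency``
    demotes a SNP to invariant when the minor-allele frequency of the counts
    merged across passed samples falls below it.
    """

    min_count: int = 0
    min_read_depth: int = 0
    max_read_depth: int = 0
    max_deletion_fraction: float = 0.0  # 0 = off
    only_snps: bool = False
    only_biallelic_snps: bool = False
    min_allele_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.min_read_depth and self.max_read_depth \
                and self.min_read_depth > self.max_read_depth:
            raise ValueError("min_read_depth > max_read_depth")


def apply_region_filter(stream: Iterable[Variant], regions: RegionList,
                        invert: bool = False) -> Iterator[Variant]:
    """Keep only positions inside (or, inverted, outside) the region list.

    Removed positions vanish from the stream and never reach any downstream
    tally.
    """
    for v in stream:
        inside = (v.chromosome, v.position) in regions
        if inside != invert:
            yield v


def apply_mask(variant: Variant, mask: Mask,
               sample_index: Optional[int] = None) -> Variant:
    """Mark masked-out positions as filtered, in place.

    A global mask filters the whole variant; a per-sample mask (``sample_index``
    given) filters only that sample column.  The position stays in the stream.
    """
    valid = mask.is_valid(variant.chromosome, variant.position)
    if valid:
        return variant
    if sample_index is None and mask.scope == "global":
        variant.mark_filtered(FilterReason.MASKED)
        for s in variant.samples:
            s.mark_filtered(FilterReason.MASKED)
    else:
        idx = sample_index if sample_index is not None else 0
        variant.samples[idx].mark_filtered(FilterReason.MASKED)
    return variant


def apply_sample_numeric_filters(variant: Variant, cfg: SampleFilterConfig) -> Variant:
    """Zero rare base tallies and filter samples on depth/deletion bounds."""
    for s in variant.samples:
        if not s.passed:
            continue
        if cfg.min_count > 0:
            for attr in ("a_count", "c_count", "g_count", "t_count"):
                if 0 < getattr(s, attr) < cfg.min_count:
                    setattr(s, attr, 0)
        depth = s.read_depth
        if cfg.min_read_depth and depth < cfg.min_read_depth:
            s.mark_filtered(FilterReason.LOW_DEPTH)
        elif cfg.max_read_depth and depth > cfg.max_read_depth:
            s.mark_filtered(FilterReason.HIGH_DEPTH)
        elif cfg.max_deletion_fraction > 0 and (depth + s.del_count) > 0 \
                and s.del_count / (depth + s.del_count) > cfg.max_deletion_fraction:
            s.mark_filtered(FilterReason.DELETION)
    return variant


def classify_site(variant: Variant, cfg: Optional[SampleFilterConfig] = None) -> SiteClass:
    """Classify a site from counts merged over passed samples.

    Zero nonzero bases → missing; one → invariant; two → biallelic SNP;
    three or more → multiallelic SNP.  A SNP whose merged minor-allele
    frequency is below ``min_allele_frequency`` is demoted to invariant.
    """
    merged = variant.merged_counts(passed_only=True)
    counts = merged.base_counts()
    nonzero = sum(1 for c in counts if c > 0)
    if nonzero == 0:
        return SiteClass.MISSING
    if nonzero == 1:
        return SiteClass.INVARIANT
    cls = SiteClass.SNP_BIALLELIC if nonzero == 2 else SiteClass.SNP_MULTIALLELIC
    if cfg is not None and cfg.min_allele_frequency > 0:
        total = sum(counts)
        maf = (total - max(counts)) / total
        if maf < cfg.min_allele_frequency:
            return SiteClass.INVARIANT
    return cls


def subsample_counts(counts: SampleCounts, max_depth: int, method: str = "rescale",
                     rng: Optional[np.random.Generator] = None) -> SampleCounts:
    """Limit a sample's read depth to ``max_depth``.

    ``subsample-without-replacement`` draws ``max_depth`` reads by a
    multivariate hypergeometric draw, ``subsample-with-replacement`` by a
    multinomial draw, and ``rescale`` scales proportionally with
    largest-remainder rounding so the result sums exactly to ``max_depth``.
    N and DEL tallies are rescaled proportionally in every method.  Depth at
    or under the threshold is returned unchanged.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    depth = counts.read_depth
    if depth <= max_depth:
        return counts
    base = np.array(counts.base_counts(), dtype=np.int64)
    if method == "rescale":
        new = _largest_remainder(base * (max_depth / depth), max_depth)
    elif method == "subsample-without-replacement":
        if rng is None:
            raise ValueError("a random generator is required for subsampling")
        new = rng.multivariate_hypergeometric(base, max_depth)
    elif method == "subsample-with-replacement":
        if rng is None:
            raise ValueError("a random generator is required for subsampling")
        new = rng.multinomial(max_depth, base / depth)
    else:
        raise ValueError(f"unknown subsampling method: {method!r}")
    scale = max_depth / depth
    out = counts.copy()
    out.a_count, out.c_count, out.g_count, out.t_count = (int(x) for x in new)
    out.n_count = int(round(counts.n_count * scale))
    out.del_count = int(round(counts.del_count * scale))
    return out


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(raw).astype(np.int64)
    remainder = int(total - floors.sum())
    if remainder > 0:
        # ties in fractional parts broken by fixed base order
        order = np.argsort(-(raw - floors), kind="stable")
        floors[order[:remainder]] += 1
    return floors


@dataclass
class CascadeTally:
    """Position bookkeeping across the whole cascade (run-summary log)."""

    read: int = 0
    region_removed: int = 0
    emitted: int = 0
    passed: int = 0
    filtered: int = 0
    snps: int = 0

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in
                ("read", "region_removed", "emitted", "passed", "filtered", "snps")}


@dataclass
class FilterCascade:
    """The full configurable cascade applied to a variant stream.

    Order: region filter → masks → numeric filters → SNP classification
    (stored on the variant as ``site_class``) → optional subsampling.
    """

    regions: Optional[RegionList] = None
    invert_regions: bool = False
    mask: Optional[Mask] = None
    sample_masks: Optional[Sequence[Optional[Mask]]] = None
    sample_cfg: SampleFilterConfig = field(default_factory=SampleFilterConfig)
    subsample_max_depth: int = 0
    subsample_method: str = "rescale"
    seed: Optional[int] = None
    tally: CascadeTally = field(default_factory=CascadeTally)

    def __call__(self, stream: Iterable[Variant]) -> Iterator[Variant]:
        rng = np.random.default_rng(self.seed) if self.seed is not None else None
        for v in stream:
            self.tally.read += 1
            if self.regions is not None:
                inside = (v.chromosome, v.position) in self.regions
                if inside == self.invert_regions:
                    self.tally.region_removed += 1
                    continue
            if self.mask is not None:
                apply_mask(v, self.mask)
            if self.sample_masks is not None:
                for i, m in enumerate(self.sample_masks):
                    if m is not None:
                        apply_mask(v, m, sample_index=i)
            apply_sample_numeric_filters(v, self.sample_cfg)
            if not any(s.passed for s in v.samples) and v.passed:
                v.mark_filtered(FilterReason.MISSING)
            site_class = classify_site(v, self.sample_cfg)
            if v.passed:
                if self.sample_cfg.only_biallelic_snps \
                        and site_class is not SiteClass.SNP_BIALLELIC:
                    v.mark_filtered(FilterReason.NOT_BIALLELIC)
                elif self.sample_cfg.only_snps and not site_class.is_snp:
                    v.mark_filtered(FilterReason.NOT_SNP)
            if self.subsample_max_depth > 0 and v.passed:
                v.samples = [
                    subsample_counts(s, self.subsample_max_depth,
                                     self.subsample_method, rng)
                    if s.passed else s
                    for s in v.samples
                ]
                site_class = classify_site(v, self.sample_cfg)
            v.site_class = site_class  # annotation consumed by windowing
            self.tally.emitted += 1
            if v.passed:
                self.tally.passed += 1
                if site_class.is_snp:
                    self.tally.snps += 1
            else:
                self.tally.filtered += 1
            yield v
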