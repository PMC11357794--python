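"""Filter cascade: regions, masks, numeric filters, SNP classes, subsampling."""

import copy

import numpy as np
import pytest

from pooldiv.filters import (FilterCascade, SampleFilterConfig, SiteClass,
                             apply_mask, apply_region_filter,
                             apply_sample_numeric_filters, classify_site,
                             subsample_counts)
from pooldiv.model import FilterReason, SampleCounts, Variant
from pooldiv.regions import Mask, RegionList


def _stream(positions):
    return [Variant("c", p, samples=[SampleCounts.from_bases(A=5)]) for p in positions]


def test_region_filter_membership_and_inversion():
    regions = RegionList.from_intervals([("c", 5, 7)])
    kept = [v.position for v in apply_region_filter(_stream(range(1, 11)), regions)]
    assert kept == [5, 6, 7]
    inv = [v.position for v in apply_region_filter(_stream(range(1, 11)), regions,
                                                   invert=True)]
    assert inv == [1, 2, 3, 4, 8, 9, 10]


def test_region_filter_empty_regions_removes_everything():
    assert list(apply_region_filter(_stream(range(1, 6)), RegionList())) == []


def test_mask_global_and_per_sample():
    mask = Mask()
    mask.add("c", 4)  # only position 4 is valid
    v5 = Variant("c", 5, samples=[SampleCounts.from_bases(A=3)])
    apply_mask(v5, mask)
    assert not v5.passed and v5.filter_reason is FilterReason.MASKED
    v4 = Variant("c", 4, samples=[SampleCounts.from_bases(A=3)])
    assert apply_mask(v4, mask).passed

    sm = Mask(scope="sample")
    sm.add("c", 1)
    v = Variant("c", 2, samples=[SampleCounts.from_bases(A=3),
                                 SampleCounts.from_bases(C=3)])
    apply_mask(v, sm, sample_index=1)
    assert v.samples[0].passed and not v.samples[1].passed
    assert v.passed  # position stays in the stream


def test_numeric_filters():
    v = Variant("c", 1, samples=[SampleCounts.from_bases(A=9, C=1)])
    apply_sample_numeric_filters(v, SampleFilterConfig(min_count=2))
    assert v.samples[0].base_counts() == (9, 0, 0, 0)
    assert v.samples[0].read_depth == 9

    v2 = Variant("c", 1, samples=[SampleCounts.from_bases(A=9)])
    apply_sample_numeric_filters(v2, SampleFilterConfig(min_read_depth=10))
    assert v2.samples[0].filter_reason is FilterReason.LOW_DEPTH

    v3 = Variant("c", 1, samples=[SampleCounts.from_bases(A=9, C=1)])
    before = v3.samples[0].base_counts()
    apply_sample_numeric_filters(v3, SampleFilterConfig(min_count=0))
    assert v3.samples[0].base_counts() == before and v3.samples[0].passed

    v4 = Variant("c", 1, samples=[SampleCounts.from_bases(A=4, D=6)])
    apply_sample_numeric_filters(v4, SampleFilterConfig(max_deletion_fraction=0.5))
    assert v4.samples[0].filter_reason is FilterReason.DELETION


def test_depth_bounds_validation():
    with pytest.raises(ValueError):
        SampleFilterConfig(min_read_depth=10, max_read_depth=5)


@pytest.mark.parametrize("bases, expected", [
    (dict(A=5, C=3), SiteClass.SNP_BIALLELIC),
    (dict(A=5), SiteClass.INVARIANT),
    (dict(), SiteClass.MISSING),
    (dict(A=5, C=3, G=2), SiteClass.SNP_MULTIALLELIC),
])
def test_classify_site(bases, expected):
    v = Variant("c", 1, samples=[SampleCounts.from_bases(**bases)])
    assert classify_site(v) is expected


def test_classify_site_maf_demotion():
    v = Variant("c", 1, samples=[SampleCounts.from_bases(A=99, C=1)])
    assert classify_site(v, SampleFilterConfig(min_allele_frequency=0.05)) \
        is SiteClass.INVARIANT
    assert classify_site(v) is SiteClass.SNP_BIALLELIC


def test_classify_site_invariant_to_sample_order_and_zero_samples(rng):
    s = [SampleCounts.from_bases(A=5, C=2), SampleCounts.from_bases(C=4)]
    v1 = Variant("c", 1, samples=s)
    v2 = Variant("c", 1, samples=list(reversed(s)) + [SampleCounts()])
    assert classify_site(v1) is classify_site(v2)


def test_subsample_rescale_exact_proportion():
    c = subsample_counts(SampleCounts.from_bases(A=30, C=10), 20)
    assert c.base_counts() == (15, 5, 0, 0)


def test_subsample_under_threshold_identity(rng):
    c = SampleCounts.from_bases(A=5)
    for method in ("rescale", "subsample-without-replacement",
                   "subsample-with-replacement"):
        assert subsample_counts(c, 10, method, rng).base_counts() == (5, 0, 0, 0)


def test_subsample_bad_max_depth():
    with pytest.raises(ValueError):
        subsample_counts(SampleCounts.from_bases(A=5), 0)


@pytest.mark.parametrize("method", ["subsample-without-replacement",
                                    "subsample-with-replacement", "rescale"])
def test_subsample_depth_cap_and_frequency_preservation(method, rng):
    """Depth never exceeds the cap; allele frequency preserved in expectation
    (hypergeometric/multinomial mean = 3/4 of 20 for A; 3-SE band)."""
    reps = 20_000
    a_sum = 0
    for _ in range(reps):
        c = subsample_counts(SampleCounts.from_bases(A=30, C=10), 20, method, rng)
        assert c.read_depth <= 20
        a_sum += c.a_count
    mean_a = a_sum / reps
    # worst-case (with replacement) SD of a single draw
    sd = np.sqrt(20 * 0.75 * 0.25)
    assert abs(mean_a - 15.0) <= 3 * sd / np.sqrt(reps)


def _cascade_fixture():
    variants = []
    for pos in range(1, 21):
        if pos % 5 == 0:
            counts = SampleCounts.from_bases(A=6, C=4)
        elif pos % 7 == 0:
            counts = SampleCounts.from_bases(A=1)
        else:
            counts = SampleCounts.from_bases(A=10)
        variants.append(Variant("c", pos, samples=[counts]))
    return variants


def test_cascade_tallies_conserve():
    cascade = FilterCascade(
        regions=RegionList.from_intervals([("c", 1, 15)]),
        sample_cfg=SampleFilterConfig(min_read_depth=2))
    out = list(cascade(_cascade_fixture()))
    t = cascade.tally
    assert t.read == 20
    assert t.read == t.region_removed + t.emitted
    assert t.emitted == t.passed + t.filtered
    assert t.snps == 3  # positions 5, 10, 15
    assert len(out) == t.emitted


def test_cascade_idempotent():
    cascade1 = FilterCascade(sample_cfg=SampleFilterConfig(min_count=2,
                                                           min_read_depth=2))
    once = list(cascade1(_cascade_fixture()))
    cascade2 = FilterCascade(sample_cfg=SampleFilterConfig(min_count=2,
                                                           min_read_depth=2))
    twice = list(cascade2(copy.deepcopy(once)))
    assert [(v.position, v.passed, v.samples[0].base_counts(), v.site_class)
            for v in once] == \
           [(v.position, v.passed, v.samples[0].base_counts(), v.site_class)
            for v in twice]


def test_cascade_biallelic_restriction():
    cascade = FilterCascade(sample_cfg=SampleFilterConfig(only_biallelic_snps=True))
    out = list(cascade(_cascade_fixture()))
    passed = [v.position for v in out if v.passed]
    assert passed == [5, 10, 15, 20]
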