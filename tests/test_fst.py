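"""F_ST components and estimators: exact values, identities, Monte-Carlo."""

import numpy as np
import pytest

from pooldiv.fst import (FstAccumulator, PairStatParts, fst_hudson,
                         fst_karlsson, fst_kofler, fst_nei, pi_between_counts,
                         pi_within_counts, site_pi_between, site_pi_total,
                         site_pi_within, window_fst)
from pooldiv.model import PoolProfile, SampleCounts, Variant
from pooldiv.windows import Window


def test_site_pi_within_exact():
    c = SampleCounts.from_bases(A=5, C=5)
    v = site_pi_within(c, c, 10, 10)
    assert v == pytest.approx((10 / 9) * (10 / 9) * 0.5)


def test_site_pi_within_monomorphic_zero():
    c = SampleCounts.from_bases(A=8)
    assert site_pi_within(c, c, 10, 10) == pytest.approx(0.0)


def test_site_pi_within_needs_depth_and_pool():
    assert site_pi_within(SampleCounts.from_bases(A=1),
                          SampleCounts.from_bases(A=5), 10, 10) is None


def test_site_pi_between_exact():
    assert site_pi_between(SampleCounts.from_bases(A=6),
                           SampleCounts.from_bases(C=4)) == pytest.approx(1.0)
    assert site_pi_between(SampleCounts.from_bases(A=5, C=5),
                           SampleCounts.from_bases(A=4, C=4)) == pytest.approx(0.5)


def test_site_pi_total_mean():
    assert site_pi_total(0.0, 1.0) == 0.5
    assert site_pi_total(0.4, 0.4) == pytest.approx(0.4)


def test_pi_total_decomposition_identity(rng):
    """(uncorrected pi_within + pi_between) / 2 equals 1 - sum(mean freq)^2."""
    for _ in range(50):
        c1 = rng.integers(0, 20, size=4).astype(float)
        c2 = rng.integers(0, 20, size=4).astype(float)
        if c1.sum() < 1 or c2.sum() < 1:
            continue
        f1, f2 = c1 / c1.sum(), c2 / c2.sum()
        piw_uncorr = 0.5 * ((1 - f1 @ f1) + (1 - f2 @ f2))
        pib = 1 - f1 @ f2
        fbar = 0.5 * (f1 + f2)
        assert 0.5 * (piw_uncorr + pib) == pytest.approx(1 - fbar @ fbar, abs=1e-12)


def _two_stage(rng, f, p, n, reps):
    k = rng.binomial(p, f, size=reps)
    m = rng.binomial(n, k / p)
    counts = np.zeros((reps, 4))
    counts[:, 0] = n - m
    counts[:, 1] = m
    return counts


@pytest.mark.parametrize("p, n", [(10, 10), (5, 50), (50, 5)])
def test_pi_within_unbiased_monte_carlo(p, n, rng):
    """Mean of the corrected estimator matches 2 f (1-f) within 3 SE."""
    f = 0.3
    reps = 100_000
    c1 = _two_stage(rng, f, p, n, reps)
    c2 = _two_stage(rng, f, p, n, reps)
    vals = pi_within_counts(c1, c2, p, p)
    expected = 2 * f * (1 - f)
    se = np.nanstd(vals) / np.sqrt(reps)
    assert abs(np.nanmean(vals) - expected) <= 3 * se


def test_pi_between_unbiased_monte_carlo(rng):
    f1t, f2t = 0.3, 0.6
    reps = 100_000
    c1 = _two_stage(rng, f1t, 10, 10, reps)
    c2 = _two_stage(rng, f2t, 10, 10, reps)
    vals = pi_between_counts(c1, c2)
    expected = 1 - (0.3 * 0.6 + 0.7 * 0.4)
    se = np.nanstd(vals) / np.sqrt(reps)
    assert abs(np.nanmean(vals) - expected) <= 3 * se


def _pair_window(count_pairs, p=10):
    variants = []
    for i, (b1, b2) in enumerate(count_pairs, 1):
        variants.append(Variant("c", i, samples=[SampleCounts.from_bases(**b1),
                                                 SampleCounts.from_bases(**b2)]))
    w = Window("c", 1, len(count_pairs))
    for v in variants:
        w.add(v, None)
    return w


def test_fixed_difference_gives_fst_one():
    w = _pair_window([(dict(A=20), dict(C=20))] * 5)
    pools = PoolProfile.uniform(10, 2, min_count=1)
    assert window_fst(w, pools, "hudson")[(0, 1)] == pytest.approx(1.0)
    assert window_fst(w, pools, "nei")[(0, 1)] == pytest.approx(1.0)


def test_no_variation_not_available():
    w = _pair_window([(dict(A=20), dict(A=20))] * 3)
    pools = PoolProfile.uniform(10, 2, min_count=1)
    for method in ("hudson", "nei", "kofler", "karlsson"):
        assert window_fst(w, pools, method)[(0, 1)] is None


def test_kofler_karlsson_approach_one_at_fixed_difference():
    w = _pair_window([(dict(A=1000), dict(C=1000))] * 5, p=100)
    pools = PoolProfile.uniform(100, 2, min_count=1)
    assert window_fst(w, pools, "kofler")[(0, 1)] == pytest.approx(1.0, abs=0.02)
    assert window_fst(w, pools, "karlsson")[(0, 1)] == pytest.approx(1.0, abs=0.02)


def test_pi_total_identity_held_by_construction(rng):
    pools = PoolProfile.uniform(20, 2, min_count=1)
    acc = FstAccumulator(pools)
    for i in range(1, 200):
        c1 = {b: int(x) for b, x in zip("ACGT", rng.integers(0, 15, 4))}
        c2 = {b: int(x) for b, x in zip("ACGT", rng.integers(0, 15, 4))}
        acc.add(Variant("c", i, samples=[SampleCounts.from_bases(**c1),
                                         SampleCounts.from_bases(**c2)]))
    part = acc.parts[(0, 1)]
    assert part.pi_total_sum == pytest.approx(
        0.5 * (part.pi_within_sum + part.pi_between_sum), abs=1e-12)


def test_hudson_at_least_nei_when_defined(rng):
    pools = PoolProfile.uniform(20, 2, min_count=1)
    acc = FstAccumulator(pools)
    for i in range(1, 500):
        c1 = {b: int(x) for b, x in zip("ACGT", rng.integers(0, 15, 4))}
        c2 = {b: int(x) for b, x in zip("ACGT", rng.integers(0, 15, 4))}
        acc.add(Variant("c", i, samples=[SampleCounts.from_bases(**c1),
                                         SampleCounts.from_bases(**c2)]))
    part = acc.parts[(0, 1)]
    h, n = fst_hudson(part), fst_nei(part)
    if h is not None and n is not None and part.pi_between_sum >= part.pi_total_sum > 0:
        assert h >= n


def test_symmetry_under_sample_swap(rng):
    pools = PoolProfile.uniform(15, 2, min_count=1)
    pairs = []
    for _ in range(100):
        c1 = {b: int(x) for b, x in zip("ACGT", rng.integers(0, 12, 4))}
        c2 = {b: int(x) for b, x in zip("ACGT", rng.integers(0, 12, 4))}
        pairs.append((c1, c2))
    w_fwd = _pair_window(pairs)
    w_rev = _pair_window([(b, a) for a, b in pairs])
    for method in ("hudson", "nei", "kofler", "karlsson"):
        a = window_fst(w_fwd, pools, method)[(0, 1)]
        b = window_fst(w_rev, pools, method)[(0, 1)]
        if a is None:
            assert b is None
        else:
            assert a == pytest.approx(b, abs=1e-12)


def test_negative_fst_not_clamped():
    parts = PairStatParts((0, 1), pi_within_sum=1.2, pi_between_sum=1.0,
                          pi_total_sum=1.1, n_sites=10)
    assert fst_hudson(parts) < 0
    assert fst_nei(parts) < 0
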