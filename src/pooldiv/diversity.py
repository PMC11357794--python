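"""Pool-seq estimators of nucleotide diversity and related statistics.

Pooled sequencing introduces two nested levels of sampling noise: a pool of
``p`` haploid genome copies is drawn from the population, and ``n`` reads are
drawn (with replacement) from the pool at each site.  Naive per-site
heterozygosity and segregating-site counts are therefore biased, and the
classical sample-size corrections of Tajima's and Watterson's estimators do
not apply directly.

Following the PoPoolation approach, each per-site contribution is divided by
a pool-aware detection denominator.  Assuming the neutral site frequency
spectrum at the pool level (derived-allele copy number ``k`` in the pool with
weight ``1/k``) and binomial read sampling, the expected per-site
heterozygosity and SNP-detection probability, given a minimum allele count
``b``, are::

    D_pi(n, p, b) = sum_{m=b}^{n-b} 2 m (n-m) / (n (n-1))
                      * sum_{k=1}^{p-1} (1/k) Binom(m; n, k/p)

    D_W(n, p, b)  = sum_{m=b}^{n-b} sum_{k=1}^{p-1} (1/k) Binom(m; n, k/p)

so that theta_pi = h / D_pi and theta_W = I(SNP detectable) / D_W are
unbiased per-site estimators of the scaled mutation rate.  As p → ∞,
D_pi(n, p, 1) → 1 and D_W(n, p, 1) → H_{n-1}, recovering the classical
sequence-based corrections.

Binomial terms are evaluated in log-space (log-gamma) so that large read
depths and pool sizes do not overflow; results are cached per (n, p, b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .model import PoolProfile, SampleCounts, Variant
from .windows import Window, window_denominator

_K_CHUNK = 1 << 17  # chunk the sum over pool copy numbers for huge pools


@lru_cache(maxsize=None)
def _pool_denominators(n: int, p: int, b: int) -> tuple[float, float]:
    """Cached (D_pi, D_W) for read depth n, pool size p, min count b.

    An empty summation range (b > n - b) returns (0, 0), meaning the site
    cannot be informative at this depth and min count.
    """
    if n < 2 or p < 2 or b < 1:
        return (0.0, 0.0)
    if b > n - b:
        return (0.0, 0.0)
    m = np.arange(b, n - b + 1, dtype=np.float64)[:, None]
    log_binom_nm = (gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1))
    pooled = np.zeros(m.shape[0])
    for k0 in range(1, p, _K_CHUNK):
        k = np.arange(k0, min(k0 + _K_CHUNK, p), dtype=np.float64)[None, :]
        f = k / p
        log_pmf = log_binom_nm + m * np.log(f) + (n - m) * np.log1p(-f)
        pooled += (np.exp(log_pmf) / k).sum(axis=1)
    mm = m[:, 0]
    d_w = float(pooled.sum())
    d_pi = float((pooled * (2.0 * mm * (n - mm) / (n * (n - 1.0)))).sum())
    return (d_pi, d_w)


def theta_pi_denominator(p: int, n: int, b: int) -> float:
    """Expected per-site heterozygosity under the neutral pool spectrum."""
    return _pool_denominators(n, p, b)[0]


def theta_w_denominator(p: int, n: int, b: int) -> float:
    """Expected per-site SNP-detection weight under the neutral pool spectrum."""
    return _pool_denominators(n, p, b)[1]


def site_heterozygosity(counts: SampleCounts) -> Optional[float]:
    """Per-site heterozygosity (n/(n-1)) * (1 - sum of squared base frequencies).

    Computed over all four base tallies; returns ``None`` for depth < 2.
    """
    n = counts.read_depth
    if n < 2:
        return None
    ssq = sum(c * c for c in counts.base_counts())
    return (n / (n - 1.0)) * (1.0 - ssq / (n * n))


def snp_detectable(counts: SampleCounts, b: int) -> bool:
    """Whether the sample's minor allele count lies in [b, n - b]."""
    n = counts.read_depth
    if n < 2:
        return False
    minor = n - max(counts.base_counts())
    return b <= minor <= n - b


def expected_pool_haplotypes(p: int, n: int) -> float:
    """Expected number of distinct pool haplotypes among n reads drawn with
    replacement from a pool of p copies; the effective sample size used by
    the normalized Tajima's D variance."""
    return p * (1.0 - (1.0 - 1.0 / p) ** n)


def tajima_constants(n_eff: float) -> tuple[float, float]:
    """Tajima's (1989) variance constants e1, e2 for sample size n_eff."""
    n = int(round(n_eff))
    if n < 3:
        raise ValueError("effective sample size must be >= 3 for normalization")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    return c1 / a1, c2 / (a1 * a1 + a2)


@dataclass
class DiversityResult:
    """Per-sample window sums and averages of the diversity estimators.

    ``tajimas_d`` is, by default, the unnormalized numerator (mean per-site
    theta_pi minus theta_W): estimates of Tajima's D from Pool-seq data rest
    on shaky statistical ground, so every result row carries a caution flag
    and normalization is opt-in.
    """

    sample: int
    theta_pi_sum: float
    theta_w_sum: float
    n_passed: int
    n_snps: int
    denominator: Optional[float]
    theta_pi: Optional[float]
    theta_w: Optional[float]
    tajimas_d: Optional[float]
    d_normalized: bool = False
    caution: str = "tajimas-d-poolseq-unreliable"


class DiversityAccumulator:
    """Streaming per-sample accumulation of theta_pi / theta_W window sums."""

    def __init__(self, pools: PoolProfile):
        self.pools = pools
        n = len(pools.pool_sizes)
        self.theta_pi_sum = [0.0] * n
        self.theta_w_sum = [0.0] * n
        self.snp_count = [0] * n

    def add(self, variant: Variant, site_class=None) -> None:
        if not variant.passed:
            return
        b = self.pools.min_count
        for i, s in enumerate(variant.samples):
            if not s.passed:
                continue
            n = s.read_depth
            if n < 2:
                continue
            p = self.pools.pool_sizes[i]
            d_pi, d_w = _pool_denominators(n, p, b)
            h = site_heterozygosity(s)
            if h and d_pi > 0.0:
                self.theta_pi_sum[i] += h / d_pi
            if d_w > 0.0 and snp_detectable(s, b):
                self.theta_w_sum[i] += 1.0 / d_w
                self.snp_count[i] += 1

    def results(self, window: Window, policy: str = "valid-loci",
                mask=None, normalize_d: bool = False) -> list[DiversityResult]:
        out = []
        for i in range(len(self.pools.pool_sizes)):
            denom = window_denominator(window, policy, mask=mask, sample_index=i)
            pi_rel = self.theta_pi_sum[i] / denom if denom else None
            w_rel = self.theta_w_sum[i] / denom if denom else None
            d = tajimas_d_value(
                self.theta_pi_sum[i], self.theta_w_sum[i], denom,
                self.snp_count[i], self.pools.pool_sizes[i],
                normalize=normalize_d)
            out.append(DiversityResult(
                sample=i,
                theta_pi_sum=self.theta_pi_sum[i],
                theta_w_sum=self.theta_w_sum[i],
                n_passed=window.passed_by_sample[i] if window.passed_by_sample else 0,
                n_snps=self.snp_count[i],
                denominator=denom,
                theta_pi=pi_rel,
                theta_w=w_rel,
                tajimas_d=d,
                d_normalized=normalize_d,
            ))
        return out


def tajimas_d_value(theta_pi_sum: float, theta_w_sum: float,
                    denom: Optional[float], n_snps: int, pool_size: int,
                    normalize: bool = False,
                    mean_depth: Optional[float] = None) -> Optional[float]:
    """Tajima's D for one window.

    Default: the unnormalized numerator, the per-site average of
    theta_pi - theta_W.  With ``normalize=True``, the numerator sums are
    divided by the square root of Tajima's variance term evaluated at the
    expected number of distinct pool haplotypes sequenced (the corrected
    PoPoolation approach); returns ``None`` when the variance term is not
    positive or not defined.
    """
    if not normalize:
        if denom is None:
            return None
        return (theta_pi_sum - theta_w_sum) / denom
    if n_snps < 1:
        return None
    n_eff = expected_pool_haplotypes(pool_size, mean_depth or 2 * pool_size)
    if n_eff < 3:
        return None
    e1, e2 = tajima_constants(n_eff)
    var = e1 * n_snps + e2 * n_snps * (n_snps - 1)
    if var <= 0:
        return None
    return (theta_pi_sum - theta_w_sum) / math.sqrt(var)


def window_theta_pi(window: Window, pools: PoolProfile) -> list[float]:
    """Per-sample window sums of the per-site theta_pi estimates."""
    acc = DiversityAccumulator(pools)
    for v in window.entries:
        acc.add(v)
    return acc.theta_pi_sum


def window_theta_w(window: Window, pools: PoolProfile) -> list[float]:
    """Per-sample window sums of the per-site theta_W estimates."""
    acc = DiversityAccumulator(pools)
    for v in window.entries:
        acc.add(v)
    return acc.theta_w_sum


def window_diversity(window: Window, pools: PoolProfile,
                     policy: str = "valid-loci", mask=None,
                     normalize_d: bool = False) -> list[DiversityResult]:
    """Full per-sample diversity results for a window holding its entries."""
    acc = DiversityAccumulator(pools)
    for v in window.entries:
        acc.add(v)
    return acc.results(window, policy=policy, mask=mask, normalize_d=normalize_d)
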