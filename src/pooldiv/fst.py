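"""Pairwise F_ST estimators for Pool-seq data.

The primary estimators build on unbiased per-site components: the pairwise
diversity within each pool, between the two pools, and across the combined
pools.  Under the two-stage Pool-seq sampling model (reads drawn with
replacement from a pool of ``p`` haploid copies drawn from the population),

    h_i = (n_i / (n_i - 1)) * (p_i / (p_i - 1)) * (1 - sum_a f_{i,a}^2)

is unbiased for the population heterozygosity of pool *i*, and

    pi_between = 1 - sum_a f_{1,a} * f_{2,a}

needs no correction since the pools are independent.  With
``pi_within = (h_1 + h_2) / 2`` and ``pi_total = (pi_within + pi_between) / 2``,
window F_ST is computed as a ratio of window sums (never a mean of per-site
ratios, which are undefined at low variation):

    F_ST(Nei)    = 1 - sum(pi_within) / sum(pi_total)
    F_ST(Hudson) = 1 - sum(pi_within) / sum(pi_between)

The PoPoolation2 estimators ("Kofler" and "Karlsson") are provided as
comparison baselines; both are biased upward at low read depth and small
pool size, which the unbiased estimators avoid.  Negative estimates are
reported as-is, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .model import PoolProfile, SampleCounts, Variant
from .windows import Window

FST_METHODS = ("hudson", "nei", "kofler", "karlsson")


# ---------------------------------------------------------------------------
# vectorized per-site component math (counts arrays of shape (..., 4))
# ---------------------------------------------------------------------------

def pi_within_counts(c1: np.ndarray, c2: np.ndarray, p1: int, p2: int) -> np.ndarray:
    """Unbiased within-pool diversity per site; NaN where a depth < 2."""
    c1 = np.asarray(c1, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    out = np.full(np.broadcast_shapes(c1.shape[:-1], c2.shape[:-1]), np.nan)
    h1 = _pool_heterozygosity(c1, p1)
    h2 = _pool_heterozygosity(c2, p2)
    ok = ~np.isnan(h1) & ~np.isnan(h2)
    out[ok] = 0.5 * (h1[ok] + h2[ok])
    return out


def _pool_heterozygosity(c: np.ndarray, p: int) -> np.ndarray:
    n = c.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssq = (c * c).sum(axis=-1) / (n * n)
        h = (n / (n - 1.0)) * (p / (p - 1.0)) * (1.0 - ssq)
    h = np.where(n >= 2, h, np.nan)
    return h


def pi_between_counts(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Between-pool diversity per site; NaN where a depth is zero."""
    c1 = np.asarray(c1, dtype=np.float64)
    c2 = np.asarray(c2, dtype=np.float64)
    n1 = c1.sum(axis=-1)
    n2 = c2.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = c1 / n1[..., None]
        f2 = c2 / n2[..., None]
        pib = 1.0 - (f1 * f2).sum(axis=-1)
    return np.where((n1 >= 1) & (n2 >= 1), pib, np.nan)


# ---------------------------------------------------------------------------
# spec-level per-site operations on SampleCounts
# ---------------------------------------------------------------------------

def site_pi_within(c1: SampleCounts, c2: SampleCounts,
                   p1: int, p2: int) -> Optional[float]:
    v = pi_within_counts(np.array(c1.base_counts()), np.array(c2.base_counts()),
                         p1, p2)
    return None if np.isnan(v) else float(v)


def site_pi_between(c1: SampleCounts, c2: SampleCounts) -> Optional[float]:
    v = pi_between_counts(np.array(c1.base_counts()), np.array(c2.base_counts()))
    return None if np.isnan(v) else float(v)


def site_pi_total(pi_within_site: float, pi_between_site: float) -> float:
    return 0.5 * (pi_within_site + pi_between_site)


# ---------------------------------------------------------------------------
# PoPoolation2 baseline components
# ---------------------------------------------------------------------------

def _kofler_site(c1, c2, p1, p2) -> Optional[tuple[float, float]]:
    """Per-site (pi_within, pi_total) of the PoPoolation2 'Kofler' estimator.

    Each pool's diversity uses the min(pool size, depth) correction factor
    rather than the full two-stage correction; pi_total is computed from the
    unweighted mean of the two pools' allele frequencies.  This is what makes
    the estimator biased upward at low depth / small pools.
    """
    n1, n2 = int(c1.sum()), int(c2.sum())
    if n1 < 2 or n2 < 2:
        return None
    m1 = min(p1, n1)
    m2 = min(p2, n2)
    if m1 < 2 or m2 < 2:
        return None
    f1 = c1 / n1
    f2 = c2 / n2
    pi1 = (1.0 - float(f1 @ f1)) * m1 / (m1 - 1.0)
    pi2 = (1.0 - float(f2 @ f2)) * m2 / (m2 - 1.0)
    fbar = 0.5 * (f1 + f2)
    mt = min(m1, m2)
    pit = (1.0 - float(fbar @ fbar)) * mt / (mt - 1.0)
    return 0.5 * (pi1 + pi2), pit


def _karlsson_site(c1, c2) -> Optional[tuple[float, float]]:
    """Per-site (N, D) terms of the Karlsson et al. (2007) estimator.

    For a biallelic site with allele counts (a_i, n_i - a_i):
    h_i = a_i (n_i - a_i) / (n_i (n_i - 1)),
    N = (f_1 - f_2)^2 - h_1 / n_1 - h_2 / n_2,  D = N + h_1 + h_2.
    Corrects read sampling but not pool sampling, hence biased upward.
    """
    total = c1 + c2
    nz = np.flatnonzero(total)
    if len(nz) != 2:
        return None
    a_idx = nz[np.argsort(-total[nz], kind="stable")]
    n1 = float(c1[a_idx].sum())
    n2 = float(c2[a_idx].sum())
    if n1 < 2 or n2 < 2:
        return None
    a1 = float(c1[a_idx[1]])
    a2 = float(c2[a_idx[1]])
    f1 = a1 / n1
    f2 = a2 / n2
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1.0))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1.0))
    num = (f1 - f2) ** 2 - h1 / n1 - h2 / n2
    return num, num + h1 + h2


# ---------------------------------------------------------------------------
# window sums and ratios
# ---------------------------------------------------------------------------

@dataclass
class PairStatParts:
    """Window sums of the per-site F_ST components for one sample pair."""

    pair: tuple[int, int]
    pi_within_sum: float = 0.0
    pi_between_sum: float = 0.0
    pi_total_sum: float = 0.0
    n_sites: int = 0
    kofler_within_sum: float = 0.0
    kofler_total_sum: float = 0.0
    kofler_sites: int = 0
    karlsson_num_sum: float = 0.0
    karlsson_den_sum: float = 0.0
    karlsson_sites: int = 0


def fst_nei(parts: PairStatParts) -> Optional[float]:
    """Nei-type F_ST = 1 - pi_within / pi_total over window sums."""
    if parts.pi_total_sum <= 0.0:
        return None
    return 1.0 - parts.pi_within_sum / parts.pi_total_sum


def fst_hudson(parts: PairStatParts) -> Optional[float]:
    """Hudson-type F_ST = 1 - pi_within / pi_between over window sums."""
    if parts.pi_between_sum <= 0.0:
        return None
    return 1.0 - parts.pi_within_sum / parts.pi_between_sum


def fst_kofler(parts: PairStatParts) -> Optional[float]:
    """PoPoolation2 'Kofler' F_ST = (pi_total - pi_within) / pi_total."""
    if parts.kofler_sites == 0 or parts.kofler_total_sum <= 0.0:
        return None
    return (parts.kofler_total_sum - parts.kofler_within_sum) / parts.kofler_total_sum


def fst_karlsson(parts: PairStatParts) -> Optional[float]:
    """Karlsson et al. (2007) ratio-of-sums F_ST."""
    if parts.karlsson_sites == 0 or parts.karlsson_den_sum <= 0.0:
        return None
    return parts.karlsson_num_sum / parts.karlsson_den_sum


FST_FUNCS = {"nei": fst_nei, "hudson": fst_hudson,
             "kofler": fst_kofler, "karlsson": fst_karlsson}


class FstAccumulator:
    """Streaming accumulation of per-pair F_ST component sums over a window."""

    def __init__(self, pools: PoolProfile,
                 pairs: Optional[Sequence[tuple[int, int]]] = None):
        self.pools = pools
        n = len(pools.pool_sizes)
        self.pairs = list(pairs) if pairs is not None else list(combinations(range(n), 2))
        self.parts = {pair: PairStatParts(pair) for pair in self.pairs}

    def add(self, variant: Variant, site_class=None) -> None:
        if not variant.passed:
            return
        for pair in self.pairs:
            i, j = pair
            s1, s2 = variant.samples[i], variant.samples[j]
            if not (s1.passed and s2.passed):
                continue
            c1 = np.array(s1.base_counts(), dtype=np.float64)
            c2 = np.array(s2.base_counts(), dtype=np.float64)
            p1 = self.pools.pool_sizes[i]
            p2 = self.pools.pool_sizes[j]
            piw = pi_within_counts(c1, c2, p1, p2)
            pib = pi_between_counts(c1, c2)
            part = self.parts[pair]
            if not (np.isnan(piw) or np.isnan(pib)):
                piw_f = float(piw)
                pib_f = float(pib)
                part.pi_within_sum += piw_f
                part.pi_between_sum += pib_f
                part.pi_total_sum += 0.5 * (piw_f + pib_f)
                part.n_sites += 1
            kof = _kofler_site(c1, c2, p1, p2)
            if kof is not None:
                part.kofler_within_sum += kof[0]
                part.kofler_total_sum += kof[1]
                part.kofler_sites += 1
            kar = _karlsson_site(c1, c2)
            if kar is not None:
                part.karlsson_num_sum += kar[0]
                part.karlsson_den_sum += kar[1]
                part.karlsson_sites += 1

    def results(self, method: str = "hudson") -> dict[tuple[int, int], Optional[float]]:
        if method not in FST_FUNCS:
            raise ValueError(f"unknown F_ST method {method!r} (one of {FST_METHODS})")
        fn = FST_FUNCS[method]
        return {pair: fn(part) for pair, part in self.parts.items()}


def window_fst(window: Window, pools: PoolProfile, method: str = "hudson",
               pairs: Optional[Sequence[tuple[int, int]]] = None
               ) -> dict[tuple[int, int], Optional[float]]:
    """Pairwise window F_ST from a window holding its entries."""
    acc = FstAccumulator(pools, pairs)
    for v in window.entries:
        acc.add(v)
    return acc.results(method)
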