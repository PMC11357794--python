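"""Synthetic Pool-seq data with the exact two-stage sampling structure the
estimators correct for.

Stage 1 draws the derived-allele copy number of a pool of ``p`` haploid
genome copies from the population allele frequency (Binomial(p, f)); stage 2
draws ``n`` reads with replacement from the pool (Binomial(n, k/p)).
Optional sequencing error flips each read to a uniformly chosen different
base with probability ``e``.  Each generated dataset ships with a truth
table of the latent frequencies, so estimator recovery can be checked
without external data.

For the single-population neutral generator the site frequency spectrum is
placed directly at the pool level: segregating sites carry pool copy number
``k`` with weight 1/k (k = 1..p-1), which is exactly the neutral pool-level
spectrum obtained by integrating Binomial pool sampling against the
continuous 1/f density.  Reads are then drawn binomially from k/p.  For the
two-population generator, population frequencies are drawn around a shared
ancestral frequency from a Balding–Nichols distribution with the target
F_ST as its parameter, and both sampling stages are applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import BASES, SampleCounts, Variant

_HARMONIC_CACHE: dict[int, float] = {}


def harmonic(n: int) -> float:
    """H_n = sum_{i=1}^{n} 1/i."""
    if n not in _HARMONIC_CACHE:
        _HARMONIC_CACHE[n] = float(np.sum(1.0 / np.arange(1, n + 1)))
    return _HARMONIC_CACHE[n]


@dataclass
class SimConfig:
    """Study conditions for a simulated Pool-seq dataset.

    ``theta`` is the per-site scaled mutation rate driving the neutral SFS;
    ``depth`` is either the fixed read depth or the Poisson mean, depending
    on ``depth_distribution``; ``error_rate`` is the per-read-base
    substitution error probability; ``fst`` is the Balding–Nichols
    differentiation parameter for two-population datasets.
    """

    n_sites: int = 10_000
    theta: float = 0.01
    freqs: Optional[Sequence[float]] = None
    pool_size: int = 100
    depth: int = 50
    depth_distribution: str = "fixed"  # fixed | poisson
    error_rate: float = 0.0
    n_populations: int = 1
    fst: float = 0.0
    ancestral_freq_bounds: tuple[float, float] = (0.05, 0.95)
    chromosome: str = "sim1"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.pool_size < 2:
            raise ValueError("need n_sites >= 1 and pool_size >= 2")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("target F_ST must be in [0, 1)")
        if self.depth_distribution not in ("fixed", "poisson"):
            raise ValueError("depth_distribution must be 'fixed' or 'poisson'")


@dataclass
class SiteTruth:
    """Latent state behind one simulated sample tally."""

    freq: float  # population derived-allele frequency
    k: int       # derived copies in the pool
    m: int       # derived reads before sequencing error


def simulate_site(freq: float, pool_size: int, depth: int, error_rate: float,
                  rng: np.random.Generator, ref: str = "A", alt: str = "C",
                  ) -> tuple[SampleCounts, SiteTruth]:
    """Two-stage draw of one sample tally at one site."""
    k = int(rng.binomial(pool_size, freq))
    m = int(rng.binomial(depth, k / pool_size))
    counts = _assemble_counts(np.array([depth - m]), np.array([m]),
                              np.array([BASES.index(ref)]),
                              np.array([BASES.index(alt)]),
                              error_rate, rng)[0]
    return counts, SiteTruth(freq=freq, k=k, m=m)


def _assemble_counts(ref_reads: np.ndarray, alt_reads: np.ndarray,
                     ref_idx: np.ndarray, alt_idx: np.ndarray,
                     error_rate: float, rng: np.random.Generator
                     ) -> list[SampleCounts]:
    """Vectorized conversion of (ref, alt) read numbers into base tallies,
    applying uniform substitution errors."""
    n = len(ref_reads)
    tallies = np.zeros((n, 4), dtype=np.int64)
    rows = np.arange(n)
    if error_rate > 0.0:
        err_ref = rng.binomial(ref_reads, error_rate)
        err_alt = rng.binomial(alt_reads, error_rate)
        np.add.at(tallies, (rows, ref_idx), ref_reads - err_ref)
        np.add.at(tallies, (rows, alt_idx), alt_reads - err_alt)
        for reads_err, src_idx in ((err_ref, ref_idx), (err_alt, alt_idx)):
            total_err = int(reads_err.sum())
            if total_err == 0:
                continue
            # each errored read lands uniformly on one of the 3 other bases
            targets = rng.integers(0, 3, size=total_err)
            site_of = np.repeat(rows, reads_err)
            others = np.array([[b for b in range(4) if b != s]
                               for s in src_idx[site_of]])
            np.add.at(tallies, (site_of, others[np.arange(total_err), targets]), 1)
    else:
        np.add.at(tallies, (rows, ref_idx), ref_reads)
        np.add.at(tallies, (rows, alt_idx), alt_reads)
    return [SampleCounts(a_count=int(t[0]), c_count=int(t[1]),
                         g_count=int(t[2]), t_count=int(t[3]))
            for t in tallies]


def _depths(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.depth_distribution == "poisson":
        return rng.poisson(cfg.depth, size=n)
    return np.full(n, cfg.depth, dtype=np.int64)


def _neutral_pool_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-site derived copy number in the pool under the neutral SFS.

    0 marks monomorphic sites; segregating sites get k in 1..p-1 with
    probability proportional to 1/k."""
    p = cfg.pool_size
    p_seg = min(1.0, cfg.theta * harmonic(p - 1))
    seg = rng.random(cfg.n_sites) < p_seg
    k = np.zeros(cfg.n_sites, dtype=np.int64)
    ks = np.arange(1, p)
    weights = (1.0 / ks) / harmonic(p - 1)
    k[seg] = rng.choice(ks, size=int(seg.sum()), p=weights)
    return k


def simulate_neutral_dataset(cfg: SimConfig,
                             rng: Optional[np.random.Generator] = None
                             ) -> tuple[list[Variant], pd.DataFrame]:
    """One-population neutral dataset: variants plus a per-site truth table.

    Deterministic given the seed; positions are 1..n_sites on one
    chromosome.  The truth table records the pool-level derived frequency
    and the generating theta (as ``truth.attrs['theta']``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.pool_size
    if cfg.freqs is not None:
        freqs = np.asarray(cfg.freqs, dtype=np.float64)
        if len(freqs) != cfg.n_sites:
            raise ValueError("freqs must have one entry per site")
        k = rng.binomial(p, freqs)
    else:
        k = _neutral_pool_counts(cfg, rng)
    depths = _depths(cfg, rng, cfg.n_sites)
    m = rng.binomial(depths, k / p)
    alt_idx = rng.integers(1, 4, size=cfg.n_sites)  # ref fixed to A
    ref_idx = np.zeros(cfg.n_sites, dtype=np.int64)
    samples = _assemble_counts(depths - m, m, ref_idx, alt_idx,
                               cfg.error_rate, rng)
    variants = [
        Variant(chromosome=cfg.chromosome, position=i + 1, ref_base="A",
                alt_base=BASES[alt_idx[i]], samples=[samples[i]])
        for i in range(cfg.n_sites)
    ]
    truth = pd.DataFrame({
        "chromosome": cfg.chromosome,
        "position": np.arange(1, cfg.n_sites + 1),
        "pool_freq": k / p,
        "pool_count": k,
        "derived_reads": m,
        "depth": depths,
    })
    truth.attrs["theta"] = cfg.theta
    return variants, truth


def _ancestral_freqs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Neutral-SFS (density 1/f) ancestral frequencies on a truncated range,
    sampled by inverse CDF: f = a * (b/a)**u."""
    a, b = cfg.ancestral_freq_bounds
    u = rng.random(cfg.n_sites)
    return a * (b / a) ** u


def simulate_pair_dataset(cfg: SimConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> tuple[list[Variant], pd.DataFrame]:
    """Two-population dataset with a known differentiation level.

    Population frequencies are Balding–Nichols draws around a shared
    ancestral frequency with parameter ``cfg.fst`` (at F_ST = 0 both
    populations share the ancestral frequency exactly), followed by the full
    two-stage Pool-seq sampling per population.  The truth table carries the
    latent frequencies; see :func:`realized_pair_truth` for the per-site
    diversity components they imply.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = cfg.pool_size
    f_anc = _ancestral_freqs(cfg, rng)
    if cfg.fst > 0.0:
        shape = (1.0 - cfg.fst) / cfg.fst
        f1 = rng.beta(f_anc * shape, (1.0 - f_anc) * shape)
        f2 = rng.beta(f_anc * shape, (1.0 - f_anc) * shape)
    else:
        f1 = f_anc.copy()
        f2 = f_anc.copy()
    alt_idx = rng.integers(1, 4, size=cfg.n_sites)
    ref_idx = np.zeros(cfg.n_sites, dtype=np.int64)
    cols = []
    latent = {}
    for name, f in (("pop1", f1), ("pop2", f2)):
        k = rng.binomial(p, f)
        depths = _depths(cfg, rng, cfg.n_sites)
        m = rng.binomial(depths, k / p)
        cols.append(_assemble_counts(depths - m, m, ref_idx, alt_idx,
                                     cfg.error_rate, rng))
        latent[name] = (k, m, depths)
    variants = [
        Variant(chromosome=cfg.chromosome, position=i + 1, ref_base="A",
                alt_base=BASES[alt_idx[i]],
                samples=[cols[0][i], cols[1][i]])
        for i in range(cfg.n_sites)
    ]
    truth = pd.DataFrame({
        "chromosome": cfg.chromosome,
        "position": np.arange(1, cfg.n_sites + 1),
        "f_ancestral": f_anc,
        "f_pop1": f1,
        "f_pop2": f2,
        "pool_count_pop1": latent["pop1"][0],
        "pool_count_pop2": latent["pop2"][0],
    })
    truth.attrs["fst"] = cfg.fst
    return variants, truth


def realized_pair_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Latent per-site diversity components implied by the true population
    frequencies: pi_within, pi_between and pi_total on the heterozygosity
    scale.  Windowed ratio-of-sums of these columns give the realized truth
    F_ST that estimator recovery is judged against."""
    f1 = truth["f_pop1"].to_numpy()
    f2 = truth["f_pop2"].to_numpy()
    piw = 0.5 * (2.0 * f1 * (1.0 - f1) + 2.0 * f2 * (1.0 - f2))
    pib = f1 * (1.0 - f2) + f2 * (1.0 - f1)
    out = truth[["chromosome", "position"]].copy()
    out["pi_within"] = piw
    out["pi_between"] = pib
    out["pi_total"] = 0.5 * (piw + pib)
    return out


def write_dataset(variants: Iterable[Variant], truth: pd.DataFrame,
                  sync_path, truth_path=None) -> None:
    """Write a simulated dataset as a sync file plus a TSV truth table."""
    from .formats import write_sync
    with open(sync_path, "w") as out:
        write_sync(variants, out)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
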