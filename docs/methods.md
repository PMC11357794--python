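# Methods

## The sampling model

All estimators assume the standard Pool-seq generative model. At a site with
population derived-allele frequency `f`, a pool of `p` haploid genome copies
is drawn from the population (derived copies `k ~ Binomial(p, f)`), and `n`
reads are drawn **with replacement** from the pool
(`m ~ Binomial(n, k/p)`). `p` always counts haploid genome copies —
individuals × ploidy — because the estimator denominators sum over the
`p − 1` possible derived copy numbers in the pool. An option to draw reads
without replacement (hypergeometric) exists in the simulator for
sensitivity checks, but every estimator assumes the binomial form.

The minimum allele count `b` models the detection threshold below which a
read count is indistinguishable from sequencing error. It enters the
diversity denominators as the summation range `m ∈ [b, n − b]`, and the
filter cascade's `min_count` zeroes base tallies below `b` so that the
filter is the single source of truth for which counts exist; the θπ
numerator therefore uses whatever counts survive filtering rather than
applying a second internal threshold. For consistent estimates the filter's
`min_count` and the pool profile's `min_count` should be the same value
(the pipeline wires this automatically).

## Diversity estimators

Per site and sample, heterozygosity is `h = (n/(n−1))(1 − Σₐ f̂ₐ²)` over all
four base tallies (not just ref/alt). θπ adds `h / D_π(n, p, b)` and θW
adds `1 / D_W(n, p, b)` for sites whose minor count lies in `[b, n − b]`,
with

    D_π(n,p,b) = Σ_{m=b}^{n−b} [2m(n−m)/(n(n−1))] Σ_{k=1}^{p−1} (1/k)·Binom(m; n, k/p)
    D_W(n,p,b) = Σ_{m=b}^{n−b} Σ_{k=1}^{p−1} (1/k)·Binom(m; n, k/p)

These are the expected per-site heterozygosity and detection weight under
the neutral pool-level spectrum (weight `1/k` on `k` derived copies), so
both estimators are unbiased for the per-site scaled mutation rate.
Binomial terms are evaluated in log-space via log-gamma, chunked over `k`
for very large pools, and cached per `(n, p, b)` — read depth varies by
site, so the cache is hit once per distinct depth. Limits recovered in the
tests: `D_π(n, p→∞, 1) = 1`, `D_W(n, p→∞, 1) = H_{n−1}`.

**Tajima's D.** The default output is the unnormalized numerator — the
per-site average of `θ̂π − θ̂W` — because a well-calibrated variance
normalization for Pool-seq data is statistically fraught; every result row
carries a caution flag. The opt-in normalized mode divides the window
numerator by `sqrt(e₁·S + e₂·S(S−1))` with Tajima's 1989 constants
evaluated at the expected number of distinct pool haplotypes sequenced,
`n* = p(1 − (1 − 1/p)ⁿ)`, following the corrected PoPoolation approach.
This normalization should be treated as a rough studentization, not a
calibrated null distribution.

## F_ST

Per site, `ĥᵢ = (nᵢ/(nᵢ−1))(pᵢ/(pᵢ−1))(1 − Σₐ f̂ᵢₐ²)` is unbiased for the
population heterozygosity of pool *i* under the two-stage model, and
`π̂_between = 1 − Σₐ f̂₁ₐ f̂₂ₐ` is unbiased with no correction because the
pools are independent (we treat re-sequenced pools as independent samples).
`π̂_total ≡ (π̂_within + π̂_between)/2` holds identically by construction.
Window F_ST is a **ratio of sums** — per-site ratios are undefined at low
variation and ratio-of-sums is the standard low-bias choice. Multi-allelic
sites enter through the full four-base sums. Negative estimates are
reported as-is; clamping at zero would bias window means.

The comparison baselines transcribe the PoPoolation2 forms: "Kofler" uses
the `min(p, n)/(min(p, n) − 1)` correction per pool and computes π_total
from the unweighted mean of the two pools' frequencies; "Karlsson"
(Karlsson et al. 2007) sums `N = (f̂₁−f̂₂)² − h₁/n₁ − h₂/n₂` over
`D = N + h₁ + h₂` at biallelic sites. Both correct at most one sampling
stage and are therefore biased upward at low depth / small pools; the
package reproduces this on its own simulations (both ≈ +0.10 at true
F_ST = 0 with p = n = 10, while Hudson/Nei stay within 3 SE of zero).

## Pipeline semantics

- **Coordinates** are 1-based inclusive everywhere; BED input is converted
  on read. Sync columns are `A:T:C:G:N:DEL`; `N`/`DEL` are stored but
  excluded from depth and statistics. The 4-field sync dialect and `#`
  headers are accepted; all text inputs may be gzipped.
- **Ref/alt**: a declared ref base is kept; a reference genome overrides;
  otherwise the two most common bases are used, ties broken alphabetically
  (A<C<G<T) for deterministic output. Ref-base conflicts between merged
  input files are an error unless a reference genome arbitrates.
- **Pileup** base columns are counted only when their quality character
  decodes (Sanger offset 33 by default) to at least the threshold; this is
  applied uniformly to match/mismatch, deletion (`*`) and skip (`><`)
  columns.
- **Filter cascade order is fixed**: regions (positions removed from the
  stream) → masks (positions marked invalid but kept, so window
  denominators can count them) → per-sample numeric filters → SNP
  classification on counts merged across passed samples → optional depth
  subsampling. The cascade is idempotent. The minor-allele-frequency filter
  is evaluated on merged counts and applied after the biallelic
  restriction. Depth subsampling offers hypergeometric (without
  replacement), multinomial (with replacement) and deterministic
  largest-remainder rescaling; all preserve allele frequency in
  expectation.
- **Windows**: interval windows are anchored at position 1 per chromosome;
  without chromosome lengths the trailing window is truncated at the last
  observed position and trailing empty windows are not emitted; with
  lengths, empty windows appear with zero tallies. SNP-count windows take
  their bounds from their first/last SNP; positions between windows are
  unassigned. Region windows report the region bounds and may share
  positions when regions overlap. Single-SNP, chromosome and genome windows
  stream with constant per-position memory when used with a statistics
  accumulator. The default averaging policy is **valid loci** (positions
  passing all filters), the recommended choice when coverage is adequate;
  per-sample statistics use per-sample valid-loci counts.

## The simulator

The generator emulates exactly the two-stage sampling the estimators
correct for, plus uniform base-substitution sequencing error (indel errors
are out of scope). For the one-population neutral dataset the SFS is placed
directly at the pool level: segregating sites carry pool copy number `k`
with weight `1/k` — the exact pool-level neutral spectrum, since
integrating `Binomial(k; p, f)` against the continuous `1/f` density gives
weight `1/k` — and reads are drawn binomially from `k/p`. Adding a second
explicit pool-sampling stage on top would double-count pool noise. A site
is segregating with probability `θ·H_{p−1}`. For the two-population
dataset, ancestral frequencies follow the `1/f` density truncated to
[0.05, 0.95] (inverse-CDF sampled), population frequencies are
Balding–Nichols draws with the target F_ST as parameter (at F_ST = 0 the
populations share frequencies exactly), and both sampling stages are
applied per population. Truth tables carry the latent frequencies so
realized window F_ST can be computed for paired comparisons.

What the simulator does **not** emulate: linkage (sites are independent, so
window-to-window variance is smaller than for real genomes), demographic
structure beyond the island model, coverage biases (GC, mapping), and
non-uniform error profiles. Passing recovery tests therefore validates the
estimator algebra under the assumed sampling model, not robustness to real
data artifacts.

## Problem sizes and numerical choices

Validation runs use 10⁵ sites (θ recovery, windows of 500 sites) and
2×10⁴ sites per F_ST condition, with 10⁵ replicates for the Monte-Carlo
unbiasedness checks — sizes chosen so that Monte-Carlo standard errors are
well below the effect sizes being tested while a full run stays fast on one
core. Statistical assertions use 3-SE bands; the denominator oracle
comparison demands ≤ 1e-10 relative error (observed: ~4e-14) over
`n, p ∈ 2..60`, `b ∈ 1..3`; the large-`p` limits are checked at `p = 10⁶`
to 1e-3. Zero window denominators yield "not available" (`nan` in output),
never division by zero. `b > n − b` marks a site uninformative
(denominator 0, contribution skipped). All randomness flows from explicit
seeds; subsampling requires a generator argument so no hidden global state
exists.

## Known limitations

- Direct SAM/BAM/CRAM and VCF ingestion is delegated to upstream
  conversion (samtools mpileup); map/bim and VCF region lists are likewise
  out of scope.
- Tajima's D for Pool-seq is reported with a caution flag for the reasons
  above; the pre-2013 buggy PoPoolation behaviour is deliberately not
  reproduced.
- f-statistics, multi-population (>2) F_ST decompositions and indel-aware
  statistics are not implemented.
- Masks are stored as per-chromosome position sets; genome-scale masks with
  hundreds of millions of valid positions would need a bitmap
  representation.
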