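"""Independent reference implementations used only as test oracles.

These deliberately take the naive route — direct double summation with
exact binomial coefficients, and a regex-based pileup tokenizer — so they
share no code path with the package's optimized implementations.
"""

from __future__ import annotations

import math
import re

import numpy as np


def naive_pool_denominators(n: int, p: int, b: int) -> tuple[float, float]:
    """(D_pi, D_W) by direct double summation with exact binomial pmf terms."""
    if b > n - b:
        return 0.0, 0.0
    ks = np.arange(1, p, dtype=np.float64)
    f = ks / p
    d_pi = 0.0
    d_w = 0.0
    for m in range(b, n - b + 1):
        pmf = math.comb(n, m) * np.power(f, m) * np.power(1.0 - f, n - m)
        inner = float(np.sum(pmf / ks))
        d_w += inner
        d_pi += inner * 2.0 * m * (n - m) / (n * (n - 1.0))
    return d_pi, d_w


_PILEUP_TOKEN = re.compile(
    r"\^.|\$|[+-](\d+)|[.,]|[ACGTNacgtn]|\*|[><]")


def naive_pileup_decode(ref: str, bases: str, quals: str,
                        min_base_quality: int = 0, quality_offset: int = 33
                        ) -> dict[str, int]:
    """Regex-tokenizing pileup decoder; returns {A,C,G,T,N,DEL} tallies."""
    counts = {b: 0 for b in ("A", "C", "G", "T", "N", "DEL")}
    qi = 0
    i = 0
    while i < len(bases):
        m = _PILEUP_TOKEN.match(bases, i)
        if m is None:
            raise ValueError(f"cannot tokenize pileup at column {i}: {bases[i:]!r}")
        tok = m.group(0)
        i = m.end()
        if tok.startswith("^") or tok == "$":
            continue
        if tok[0] in "+-":
            i += int(m.group(1))
            continue
        q = ord(quals[qi]) - quality_offset
        qi += 1
        if q < min_base_quality:
            continue
        if tok in ".,":
            key = ref.upper() if ref.upper() in "ACGT" else "N"
            counts[key] += 1
        elif tok.upper() in "ACGT":
            counts[tok.upper()] += 1
        elif tok == "*":
            counts["DEL"] += 1
        else:
            counts["N"] += 1
    if qi != len(quals):
        raise ValueError("quality string length mismatch")
    return counts


def random_pileup_sample(rng: np.random.Generator, ref: str) -> tuple[str, str]:
    """A random well-formed (base string, quality string) pileup pair."""
    n = int(rng.integers(1, 30))
    bases = []
    quals = []
    for _ in range(n):
        if rng.random() < 0.15:
            bases.append("^" + chr(int(rng.integers(33, 90))))
        r = rng.random()
        if r < 0.5:
            bases.append("." if rng.random() < 0.5 else ",")
        elif r < 0.85:
            bases.append(str(rng.choice(list("ACGTacgt"))))
        elif r < 0.92:
            bases.append("*")
        elif r < 0.96:
            bases.append(str(rng.choice(list("Nn><"))))
        else:
            bases.append("." )
        quals.append(chr(int(rng.integers(33, 74))))
        if rng.random() < 0.1:
            ln = int(rng.integers(1, 5))
            seq = "".join(rng.choice(list("ACGT"), size=ln))
            bases.append(("+" if rng.random() < 0.5 else "-") + str(ln) + seq)
        if rng.random() < 0.1:
            bases.append("$")
    return "".join(bases), "".join(quals)
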