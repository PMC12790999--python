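"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by direct enumeration so
they stay independent of the vectorised implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfphase.simulate import SimConfig


@pytest.fixture(scope="session")
def base_config() -> SimConfig:
    return SimConfig(seed=7, genome_length=50_000, n_genes=4)


def wps_bruteforce(starts, ends, span_start, span_end, window=120):
    """O(F x P) windowed protection score by direct per-position counting."""
    half = window // 2
    out = np.zeros(span_end - span_start, dtype=np.int64)
    for i, p in enumerate(range(span_start, span_end)):
        w0, w1 = p - half, p + half
        score = 0
        for s, e in zip(starts, ends):
            if s <= w0 and e >= w1:
                score += 1
            elif (w0 < s < w1) or (w0 < e < w1):
                score -= 1
        out[i] = score
    return out


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def kmer_freq_bruteforce(seq: str, k: int = 4, both_strands: bool = True) -> dict:
    """Exact k-mer frequencies by enumerating every window on both strands."""
    counts: dict[str, int] = {}
    strands = [seq, revcomp(seq)] if both_strands else [seq]
    for s in strands:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if all(b in "ACGT" for b in kmer):
                counts[kmer] = counts.get(kmer, 0) + 1
    total = sum(counts.values())
    return {m: c / total for m, c in counts.items()}


def end_motif_tally_bruteforce(fragments, genome: str, k: int = 4) -> dict:
    """Pooled 5' end-motif frequencies by per-fragment slicing."""
    counts: dict[str, int] = {}
    for _, row in fragments.iterrows():
        s, e = int(row["start"]), int(row["end"])
        if e - s < k or s < 0 or e > len(genome):
            continue
        for motif in (genome[s : s + k], revcomp(genome[e - k : e])):
            if all(b in "ACGT" for b in motif):
                counts[motif] = counts.get(motif, 0) + 1
    total = sum(counts.values())
    return {m: c / total for m, c in counts.items()}


def fisher_two_sided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration over all
    tables with the observed margins."""
    from math import comb

    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def prob(x: int) -> float:
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)
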