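"""Oriented 4-bp fragment end-motif extraction and differential usage.

The terminal bases of a cfDNA fragment record where a nuclease cut. Both
ends are reported 5'->3': the upstream end is read directly off the
reference forward strand, the downstream end is the reverse complement of
the last k reference bases (that end's 5'->3' sequence lies on the minus
strand). Observed motif frequencies are compared with the genome-expected
k-mer frequencies (both strands), and per-motif group contrasts / covariate
correlations use Wilcoxon or Pearson with BH correction across motifs.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from ._stats import feature_correlations, feature_rank_tests

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_MOTIFS",
    "reverse_complement",
    "fragment_end_motifs",
    "motif_frequencies",
    "motif_frequency_table",
    "expected_motif_frequencies",
    "differential_motif_usage",
    "motif_covariate_correlation",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALL_MOTIFS = ["".join(m) for m in itertools.product("ACGT", repeat=4)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _chrom_seq(genome, chrom: str) -> str:
    """Fetch one chromosome as an uppercase string.

    Accepts a plain string (single-chromosome genome), a dict of name ->
    sequence, or any mapping-style FASTA object (e.g. pyfaidx.Fasta).
    """
    if isinstance(genome, str):
        return genome.upper()
    seq = genome[chrom]
    return str(seq[:]).upper() if not isinstance(seq, str) else seq.upper()


def fragment_end_motifs(fragment, genome, k: int = 4) -> tuple[str | None, str | None]:
    """5' end motifs of one fragment, both reported 5'->3'.

    ``fragment`` is (chrom, start, end) or a row with those fields. Returns
    (motif5, motif3); a motif is None when it falls out of genome bounds or
    contains an ambiguous base.
    """
    try:
        chrom, start, end = fragment["chrom"], int(fragment["start"]), int(fragment["end"])
    except (TypeError, IndexError, KeyError):
        chrom, start, end = fragment[0], int(fragment[1]), int(fragment[2])
    seq = _chrom_seq(genome, chrom)
    if end - start < k:
        return None, None
    if start < 0 or end > len(seq):
        logger.warning("fragment %s:%d-%d out of genome bounds, skipped", chrom, start, end)
        return None, None
    m5 = seq[start : start + k]
    m3 = reverse_complement(seq[end - k : end])
    if any(b not in "ACGT" for b in m5):
        m5 = None
    if any(b not in "ACGT" for b in m3):
        m3 = None
    return m5, m3


def motif_frequencies(fragments: pd.DataFrame, genome, k: int = 4, pool_ends: bool = True):
    """Motif frequency vector for one sample's fragments.

    Both end motifs of every fragment are attempted; motifs containing N or
    out of bounds are skipped and counted in ``skipped``. Frequencies are
    normalised over counted motifs and sum to 1.

    Returns (frequencies: Series over the 256 motifs, counted, skipped);
    with ``pool_ends=False`` frequencies is a DataFrame with columns
    ``end5``/``end3``.
    """
    counts5: dict[str, int] = {}
    counts3: dict[str, int] = {}
    skipped = 0
    by_chrom = fragments.groupby("chrom", sort=False) if len(fragments) else []
    for chrom, sub in by_chrom:
        seq = _chrom_seq(genome, chrom)
        L = len(seq)
        for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if end - start < k or start < 0 or end > L:
                skipped += 2
                continue
            m5 = seq[start : start + k]
            m3 = reverse_complement(seq[end - k : end])
            for motif, counts in ((m5, counts5), (m3, counts3)):
                if any(b not in "ACGT" for b in motif):
                    skipped += 1
                else:
                    counts[motif] = counts.get(motif, 0) + 1
    c5 = pd.Series(counts5, dtype=float).reindex(ALL_MOTIFS, fill_value=0.0)
    c3 = pd.Series(counts3, dtype=float).reindex(ALL_MOTIFS, fill_value=0.0)
    counted = int(c5.sum() + c3.sum())
    if counted == 0:
        raise ValueError("no end motifs could be counted")
    if pool_ends:
        freq = (c5 + c3) / counted
        freq.name = "frequency"
        return freq, counted, skipped
    table = pd.DataFrame({"end5": c5 / max(c5.sum(), 1), "end3": c3 / max(c3.sum(), 1)})
    return table, counted, skipped


def motif_frequency_table(fragment_sets: dict, genome, k: int = 4) -> pd.DataFrame:
    """Samples x motifs frequency table from {sample_name: fragment DataFrame}."""
    rows = {}
    for name, frags in fragment_sets.items():
        freq, _, _ = motif_frequencies(frags, genome, k=k)
        rows[name] = freq
    return pd.DataFrame(rows).T


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _kmer_counts_forward(seq: str, k: int) -> np.ndarray:
    """Counts of every length-k window on the forward sequence (N-windows excluded)."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.zeros(4**k, dtype=np.int64)
    kcodes = np.zeros(codes.size - k + 1, dtype=np.int64)
    valid = np.ones(codes.size - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : codes.size - k + 1 + j]
        kcodes = kcodes * 4 + np.where(window < 0, 0, window)
        valid &= window >= 0
    return np.bincount(kcodes[valid], minlength=4**k)


def _revcomp_permutation(k: int) -> np.ndarray:
    """Index permutation mapping each k-mer code to its reverse complement's code."""
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        digit = (codes // (4**j)) % 4  # base at position k-1-j (j-th from the right)
        rc += (3 - digit) * 4 ** (k - 1 - j)
    return rc


def expected_motif_frequencies(genome, k: int = 4, both_strands: bool = True) -> pd.Series:
    """Genome-expected k-mer frequencies by exact sliding-window counting.

    Every length-k window of the sequence is counted (windows containing N
    excluded); by default the reverse-complement strand is counted too,
    since fragment ends sample both strands. Frequencies sum to 1.
    """
    if isinstance(genome, str):
        seqs = [genome]
    else:
        seqs = [_chrom_seq(genome, c) for c in (genome.keys() if hasattr(genome, "keys") else genome)]
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        if len(seq) < k:
            continue
        counts += _kmer_counts_forward(seq, k)
    if counts.sum() == 0:
        raise ValueError(f"genome shorter than k={k}")
    if both_strands:
        counts = counts + counts[_revcomp_permutation(k)]
    motifs = ALL_MOTIFS if k == 4 else ["".join(m) for m in itertools.product("ACGT", repeat=k)]
    freq = pd.Series(counts / counts.sum(), index=motifs, name="expected_frequency")
    return freq


def differential_motif_usage(table: pd.DataFrame, labels, group1=None, group2=None) -> pd.DataFrame:
    """Per-motif Wilcoxon contrast of frequencies between two sample groups.

    Returns a DataFrame indexed by motif with log2 fold change (group1 over
    group2 means, pseudo-frequency = half the smallest nonzero frequency),
    two-sided p, and BH q across all tested motifs.
    """
    return feature_rank_tests(table, labels, group1=group1, group2=group2)


def motif_covariate_correlation(table: pd.DataFrame, covariate) -> pd.DataFrame:
    """Per-motif Pearson correlation of frequency with a clinical covariate."""
    return feature_correlations(table, covariate)
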