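"""Circulating microbial DNA: abundances, outlier filtering, group contrasts.

Non-human cfDNA reads classified to genus level are converted to abundances
(proportion of a sample's non-human reads), with genera kept only when they
reach >= 10 reads in that sample. True pathogen signals are separated from
the large contaminant background with a stringent outlier filter: an
abundance at least 3.5 SD above the pooled cohort mean. Differential
abundance between patient groups uses per-genus Wilcoxon tests with BH
correction, and concordance of flagged genera with microbiological cultures
is tested with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import feature_rank_tests

__all__ = [
    "TaxonTable",
    "OutlierCall",
    "abundance_table",
    "outlier_filter",
    "differential_abundance",
    "culture_concordance",
    "flatten_kraken_report",
]

MIN_READS = 10
OUTLIER_K = 3.5


@dataclass
class TaxonTable:
    """Per-sample genus read counts and detection-filtered abundances.

    ``abundance`` is NaN where the genus did not reach ``min_reads`` in that
    sample (a non-detection, distinct from a low signal); denominators are
    the samples' total non-human read counts, not recomputed after
    filtering.
    """

    counts: pd.DataFrame  # samples x genera, raw reads
    totals: pd.Series  # total non-human reads per sample
    abundance: pd.DataFrame  # samples x genera, NaN = below detection
    min_reads: int = MIN_READS


def abundance_table(counts: pd.DataFrame, totals: pd.Series, min_reads: int = MIN_READS) -> TaxonTable:
    """Abundances = read_count / total non-human reads, after the >= min_reads filter."""
    totals = pd.Series(totals).reindex(counts.index)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("every sample needs a positive total non-human read count")
    detected = counts >= min_reads
    abundance = counts.where(detected).div(totals, axis=0)
    return TaxonTable(counts=counts.copy(), totals=totals.astype(np.int64), abundance=abundance, min_reads=min_reads)


@dataclass
class OutlierCall:
    """(sample, genus) pairs whose abundance clears mean + k*SD of the cohort pool."""

    flagged: list[tuple[str, str]]
    threshold: float
    k: float
    mean: float
    sd: float
    flags: pd.DataFrame = field(repr=False, default=None)  # boolean samples x genera


def outlier_filter(table: TaxonTable, k: float = OUTLIER_K, log_scale: bool = False) -> OutlierCall:
    """Flag abundances at least k SD above the pooled cohort mean.

    The pool is every detected (sample, genus) abundance in the cohort —
    one distribution, one cutoff. Non-detections are excluded from the pool.
    With ``log_scale=True`` the rule is applied to log10 abundances. A
    zero-variance pool yields no flags.
    """
    values = table.abundance.to_numpy(dtype=float)
    pool = values[np.isfinite(values)]
    if pool.size < 3:
        raise ValueError("need at least 3 detected abundances")
    work = np.log10(pool) if log_scale else pool
    mean, sd = float(work.mean()), float(work.std(ddof=1))
    if np.isclose(sd, 0.0):
        flags = pd.DataFrame(False, index=table.abundance.index, columns=table.abundance.columns)
        thresh = 10**mean if log_scale else mean
        return OutlierCall(flagged=[], threshold=float(thresh), k=k, mean=mean, sd=sd, flags=flags)
    cut = mean + k * sd
    threshold = float(10**cut) if log_scale else float(cut)
    flags = table.abundance >= threshold
    flagged = [(str(s), str(g)) for s, g in flags.stack()[lambda x: x].index]
    return OutlierCall(flagged=flagged, threshold=threshold, k=k, mean=mean, sd=sd, flags=flags.fillna(False))


def differential_abundance(table: TaxonTable, labels, group1=None, group2=None) -> pd.DataFrame:
    """Per-genus Wilcoxon contrast of abundances between two sample groups.

    Non-detections enter as abundance 0 (absence is informative). Returns
    log2 fold change (pseudo-abundance guarded), two-sided p, BH q.
    """
    filled = table.abundance.fillna(0.0)
    return feature_rank_tests(filled, labels, group1=group1, group2=group2)


def culture_concordance(n_flagged_confirmed: int, n_flagged: int, n_background_confirmed: int, n_background: int) -> dict:
    """Fisher's exact test of culture confirmation in flagged vs background genera.

    Builds the 2x2 table [[flagged & confirmed, flagged & not],
    [background & confirmed, background & not]]; returns the two
    proportions, the odds ratio (Haldane 0.5 correction when a cell is
    zero), and the two-sided Fisher p.
    """
    if n_flagged < 0 or n_background < 0 or n_flagged_confirmed > n_flagged or n_background_confirmed > n_background:
        raise ValueError("inconsistent 2x2 counts")
    if n_flagged == 0 or n_background == 0:
        raise ValueError("both margins must be non-empty")
    a, b = n_flagged_confirmed, n_flagged - n_flagged_confirmed
    c, d = n_background_confirmed, n_background - n_background_confirmed
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "table": ((a, b), (c, d)),
        "proportion_flagged": a / n_flagged,
        "proportion_background": c / n_background,
        "odds_ratio": float(odds),
        "p": float(p),
    }


def flatten_kraken_report(path, rank: str = "G") -> pd.DataFrame:
    """Keep genus-level rows of a Kraken2-style report.

    Expects the standard 6-column report (percentage, clade reads, direct
    reads, rank code, taxid, name); returns a DataFrame with ``genus`` and
    ``reads`` (clade read counts) for rows at the requested rank.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                continue
            if parts[3].strip() == rank:
                rows.append((parts[5].strip(), int(parts[1])))
    return pd.DataFrame(rows, columns=["genus", "reads"])
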