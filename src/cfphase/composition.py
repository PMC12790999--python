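"""Hierarchical methylome deconvolution, genome equivalents, cellular turnover.

Cell-type proportions in a cfDNA sample are estimated by regressing its
region-level methylation vector on a reference atlas (region x cell type)
with nonnegative least squares, optionally robustified with
iteratively-reweighted Huber weights, then renormalised to the simplex.
This matches the input/output contract of reference-based robust-partial-
correlation deconvolution.

The hierarchical variant handles the common case of a solid-tissue atlas
that lacks immune resolution: the tissue atlas is first extended with a
single "immune cells" column (a weighted average of an immune atlas, each
cell type weighted by its average proportion in whole blood); the estimated
immune fraction is then split into immune cell types by a second
deconvolution against the immune atlas alone.

Genome equivalents convert proportions into absolute genomes per ml plasma:
GEQ/ml = p_i * purity * yield / 0.006, with 0.006 ng the DNA content of one
diploid genome. Turnover = GEQ/ml (cell death) over CBC cells/ml (live
cells); a ratio of 1 marks death and generation in balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "GENOME_MASS_NG",
    "merge_references",
    "deconvolve",
    "hierarchical_deconvolve",
    "geq_per_ml",
    "turnover",
    "TurnoverEstimate",
]

GENOME_MASS_NG = 0.006  # ng DNA per genome (average DNA content of a cell)

IMMUNE_COLUMN = "immune cells"


def merge_references(
    tissue_atlas: pd.DataFrame,
    immune_atlas: pd.DataFrame,
    whole_blood_weights,
) -> pd.DataFrame:
    """Tissue atlas plus one merged "immune cells" column.

    The immune column is the weighted average of the immune atlas columns,
    weights normalised to sum 1 (each immune cell type weighted by its
    average proportion in whole blood). Atlases are intersected on region
    ids; the number of dropped regions is logged.
    """
    w = pd.Series(whole_blood_weights, dtype=float).reindex(immune_atlas.columns)
    if w.isna().any():
        raise ValueError("whole_blood_weights must cover every immune atlas cell type")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with at least one positive entry")
    common = tissue_atlas.index.intersection(immune_atlas.index)
    if len(common) == 0:
        raise ValueError("tissue and immune atlases share no regions")
    dropped = (len(tissue_atlas) - len(common)) + (len(immune_atlas) - len(common))
    if dropped:
        logger.info("merge_references: %d atlas regions outside the intersection dropped", dropped)
    merged = tissue_atlas.loc[common].copy()
    merged[IMMUNE_COLUMN] = immune_atlas.loc[common].to_numpy() @ (w / w.sum()).to_numpy()
    return merged


def _huber_weights(residuals: np.ndarray, delta: float) -> np.ndarray:
    a = np.abs(residuals)
    return np.where(a <= delta, 1.0, delta / np.maximum(a, 1e-12))


def deconvolve(
    sample: pd.Series,
    atlas: pd.DataFrame,
    robust: bool = True,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> pd.Series:
    """Cell-type proportions for one sample by (robust) nonnegative least squares.

    Regions are intersected between sample and atlas; missing sample values
    are dropped pairwise. With ``robust=True`` the NNLS is iteratively
    reweighted with Huber weights (delta = 1.345 * residual MAD-scale) until
    the coefficients stabilise. Coefficients are renormalised to sum 1.

    A rank-deficient atlas is flagged with a warning carrying the condition
    number; the (unstable) estimate is still returned.
    """
    sample = sample.dropna()
    common = atlas.index.intersection(sample.index)
    if len(common) < atlas.shape[1]:
        raise ValueError("fewer shared regions than atlas cell types")
    A = atlas.loc[common].to_numpy(dtype=float)
    y = sample.loc[common].to_numpy(dtype=float)
    cond = np.linalg.cond(A)
    if cond > 1e8:
        logger.warning("atlas is near rank-deficient (condition number %.3g); estimate unstable", cond)
    coef, _ = nnls(A, y)
    if robust:
        for _ in range(max_iter):
            resid = y - A @ coef
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if scale <= 0:
                break  # exact fit: nothing to reweight
            w = np.sqrt(_huber_weights(resid, 1.345 * scale))
            new_coef, _ = nnls(A * w[:, None], y * w)
            if np.max(np.abs(new_coef - coef)) < tol:
                coef = new_coef
                break
            coef = new_coef
    total = coef.sum()
    props = coef / total if total > 0 else np.full_like(coef, 1.0 / coef.size)
    return pd.Series(props, index=atlas.columns, name=sample.name)


def hierarchical_deconvolve(
    sample: pd.Series,
    tissue_atlas: pd.DataFrame,
    immune_atlas: pd.DataFrame,
    whole_blood_weights,
    robust: bool = True,
) -> pd.Series:
    """Two-step deconvolution: tissues + merged immune column, then immune split.

    Step 1 estimates solid-tissue proportions and one aggregate immune
    fraction against the merged atlas. Step 2 splits the immune fraction
    into immune cell types by deconvolving against the immune atlas alone;
    the step-2 input is the sample minus the step-1 solid-tissue component,
    so that solid-tissue background methylation cannot masquerade as an
    immune cell type. The final vector covers tissue and immune cell types
    and sums to 1.
    """
    merged = merge_references(tissue_atlas, immune_atlas, whole_blood_weights)
    step1 = deconvolve(sample, merged, robust=robust)
    immune_fraction = float(step1[IMMUNE_COLUMN])
    tissues = step1.drop(IMMUNE_COLUMN)
    clean = sample.dropna()
    common = tissue_atlas.index.intersection(clean.index)
    tissue_component = tissue_atlas.loc[common] @ tissues.reindex(tissue_atlas.columns)
    residual = clean.loc[common] - tissue_component
    residual.name = sample.name
    step2 = deconvolve(residual, immune_atlas, robust=robust)
    out = pd.concat([tissues, immune_fraction * step2])
    out.name = sample.name
    return out


def geq_per_ml(p_i: float, purity: float, yield_ng_per_ml: float, genome_mass_ng: float = GENOME_MASS_NG) -> float:
    """Genome equivalents per ml plasma contributed by one cell type.

    GEQ/ml = p_i * purity * (yield [ng/ml] / 0.006 [ng/genome]).
    """
    if p_i < 0 or purity < 0 or yield_ng_per_ml < 0 or genome_mass_ng <= 0:
        raise ValueError("GEQ inputs must be nonnegative (genome mass positive)")
    if purity > 1:
        raise ValueError("purity is a fraction in [0, 1]")
    return p_i * purity * (yield_ng_per_ml / genome_mass_ng)


@dataclass(frozen=True)
class TurnoverEstimate:
    """Cell-death (GEQ/ml) to live-cell (cells/ml) ratio; 1 = balanced turnover."""

    geq_per_ml: float
    cells_per_ml: float

    @property
    def ratio(self) -> float:
        return self.geq_per_ml / self.cells_per_ml


def turnover(geq: float, cells_per_ml: float) -> TurnoverEstimate:
    """Cellular turnover for one cell type; requires a positive live-cell count."""
    if cells_per_ml <= 0:
        raise ValueError("cells_per_ml must be positive")
    if geq < 0:
        raise ValueError("geq must be nonnegative")
    return TurnoverEstimate(geq_per_ml=float(geq), cells_per_ml=float(cells_per_ml))
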