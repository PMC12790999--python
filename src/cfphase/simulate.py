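"""Synthetic-data generators for every input the analysis modules consume.

The generators emulate the statistical structure of plasma cfDNA data:

* a random genome with a configurable GC content;
* a TSS annotation with well-separated genes, half active / half inactive;
* fragment sets with (a) phased nucleosome arrays downstream of active
  TSSs whose positional jitter grows with nucleosome index (phasing decays
  with distance), (b) a background fragment pool drawn from a
  sub/mono/di/poly-nucleosomal length mixture, and (c) an optional cleavage
  bias towards 5'-CC end motifs;
* WPS profiles drawn directly from the damped-oscillator model plus noise;
* methylation mixtures over a reference atlas;
* genus-level read-count tables with a contaminant background and planted
  pathogens.

Every generator is a pure function of its config and seed: identical inputs
give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .oscillator import OscillatorParams, model_predict

__all__ = [
    "SimConfig",
    "generate_genome",
    "generate_genes",
    "simulate_fragments",
    "simulate_wps_direct",
    "simulate_methylation",
    "simulate_taxa",
    "simulate_reference_atlas",
]

#: background length-class bounds (bp), uniform within class
CLASS_RANGES = {
    "sub": (50, 119),
    "mono": (120, 250),
    "di": (251, 420),
    "poly": (421, 700),
}

_MIN_TSS_SPACING = 6000  # prevents 5-kb footprinting windows from overlapping


def _default_class_mix() -> dict[str, float]:
    # cohort-typical size-class proportions: mono 90.75%, di 5.2%, poly
    # 0.61%, remainder subnucleosomal
    return {"sub": 0.0344, "mono": 0.9075, "di": 0.052, "poly": 0.0061}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the structure the analyses assume: a ~167-bp
    protected (mononucleosomal) fragment length, a 187-bp nucleosome repeat
    downstream of active TSSs, a +100 bp first-nucleosome offset standing in
    for the promoter nucleosome-free region, and positional jitter that
    grows linearly with nucleosome index so phasing decays with distance.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.41
    n_genes: int = 20
    chrom: str = "chr1"
    nucleosome_repeat: int = 187
    protected_length: int = 167
    length_sd: float = 5.0
    first_nucleosome_offset: int = 100
    n_nucleosomes: int = 10
    jitter_base_sd: float = 5.0
    jitter_growth_sd: float = 2.0
    fragments_per_nucleosome: int = 50
    background_rate: float = 0.005  # fragments per bp of genome
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    cc_end_bias: float = 1.0  # odds multiplier for CC-starting 5' ends
    noise_sd: float = 0.05  # WPS units, for direct profile simulation
    active_fraction: float = 0.5

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"class_mix must sum to 1, got {total}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix proportions must be >= 0")
        if self.cc_end_bias < 0:
            raise ValueError("cc_end_bias must be >= 0")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_genome(config: SimConfig) -> str:
    """Random i.i.d. genome over {A, C, G, T} with the configured GC content."""
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = _rng(config.seed)
    gc = config.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_length, p=p)
    return bases.tobytes().decode("ascii")


def generate_genes(config: SimConfig, genome: str) -> pd.DataFrame:
    """TSS annotation: n_genes with >= 2.5 kb flanks and >= 6 kb mutual spacing.

    Positions are drawn uniformly subject to the spacing constraint (ordered
    uniform gaps), strands ~50/50, and an activity label marks which genes
    receive phased nucleosome arrays.
    """
    n = config.n_genes
    cols = ["gene_id", "chrom", "tss", "strand", "activity"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    L = len(genome)
    lo, hi = 2500, L - 2500
    slack = (hi - lo - 1) - (n - 1) * _MIN_TSS_SPACING
    if slack < 0:
        raise ValueError(f"genome of {L} bp too short for {n} genes with {_MIN_TSS_SPACING} bp spacing")
    rng = _rng(config.seed + 1)
    offsets = np.sort(rng.uniform(0, slack, size=n))
    tss = (lo + offsets + np.arange(n) * _MIN_TSS_SPACING).astype(np.int64)
    strand = rng.choice(["+", "-"], size=n)
    n_active = int(round(n * config.active_fraction))
    activity = np.array(["inactive"] * n, dtype=object)
    activity[rng.permutation(n)[:n_active]] = "active"
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "chrom": config.chrom,
            "tss": tss,
            "strand": strand,
            "activity": activity,
        }
    )


def _phased_fragments(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Nucleosome-protected fragments over active genes.

    Nucleosome n (n = 0..n_nucleosomes-1) sits at
    tss + strand_sign * (first_nucleosome_offset + n * nucleosome_repeat);
    every fragment re-draws the centre with jitter SD
    jitter_base_sd + n * jitter_growth_sd (one fragment = one cell), and a
    length ~ round(N(protected_length, length_sd)).
    """
    active = genes.loc[genes["activity"] == "active"]
    k = config.fragments_per_nucleosome
    if len(active) == 0 or k == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    tss = active["tss"].to_numpy()
    sign = np.where(active["strand"].to_numpy() == "+", 1, -1)
    nuc = np.arange(config.n_nucleosomes)
    # centres: (genes, nucleosomes) -> repeat each k times
    centres = tss[:, None] + sign[:, None] * (config.first_nucleosome_offset + nuc[None, :] * config.nucleosome_repeat)
    sds = config.jitter_base_sd + nuc * config.jitter_growth_sd
    centres = np.repeat(centres[:, :, None], k, axis=2)
    jitter = rng.normal(0.0, np.broadcast_to(sds[None, :, None], centres.shape))
    centres = (centres + jitter).ravel()
    lengths = np.maximum(np.rint(rng.normal(config.protected_length, config.length_sd, size=centres.size)), 1)
    starts = np.rint(centres - lengths / 2).astype(np.int64)
    ends = starts + lengths.astype(np.int64)
    return pd.DataFrame({"chrom": config.chrom, "start": starts, "end": ends})


def _background_fragments(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_bg = rng.poisson(config.background_rate * config.genome_length)
    if n_bg == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    which = rng.choice(len(classes), size=n_bg, p=probs)
    lows = np.array([CLASS_RANGES[c][0] for c in classes])
    highs = np.array([CLASS_RANGES[c][1] for c in classes])
    lengths = rng.integers(lows[which], highs[which] + 1)
    starts = rng.integers(0, np.maximum(config.genome_length - lengths, 1))
    return pd.DataFrame({"chrom": config.chrom, "start": starts, "end": starts + lengths})


def _apply_cc_bias(frags: pd.DataFrame, genome: str, bias: float, rng: np.random.Generator) -> pd.DataFrame:
    """Resample fragments with odds multiplied by ``bias`` when the reference
    sequence at the 5' start begins with CC (count-preserving weighted
    resampling with replacement)."""
    if len(frags) == 0 or np.isclose(bias, 1.0):
        return frags
    starts = frags["start"].to_numpy()
    ok = (starts >= 0) & (starts + 2 <= len(genome))
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    is_cc = np.zeros(len(frags), dtype=bool)
    s_ok = starts[ok]
    is_cc[ok] = (g[s_ok] == ord("C")) & (g[s_ok + 1] == ord("C"))
    w = np.where(is_cc, bias, 1.0)
    idx = rng.choice(len(frags), size=len(frags), replace=True, p=w / w.sum())
    return frags.iloc[idx].reset_index(drop=True)


def simulate_fragments(config: SimConfig, genes: pd.DataFrame, genome: str) -> pd.DataFrame:
    """Full fragment set: phased arrays at active genes + genome-wide background.

    Inactive genes receive background only (the random-arrangement control).
    Fragments extending past the genome ends are dropped.
    """
    rng = _rng(config.seed + 2)
    phased = _phased_fragments(config, genes, rng)
    background = _background_fragments(config, rng)
    frags = pd.concat([phased, background], ignore_index=True)
    if len(frags):
        frags = frags.astype({"start": np.int64, "end": np.int64})
        keep = (frags["start"] >= 0) & (frags["end"] <= config.genome_length)
        frags = frags.loc[keep].reset_index(drop=True)
        frags = _apply_cc_bias(frags, genome, config.cc_end_bias, rng)
    return frags


def simulate_wps_direct(params: OscillatorParams, grid, noise_sd: float, seed: int) -> pd.Series:
    """WPS profile drawn directly from the oscillator model plus i.i.d. noise.

    With ``noise_sd=0`` the values equal ``model_predict`` exactly. Returns a
    Series indexed by distance, ready for ``PhasingOscillatorModel``.
    """
    grid = np.asarray(grid)
    if grid.min() < -2500 or grid.max() > 2500:
        raise ValueError("grid must lie within [-2500, 2500] bp of the TSS")
    values = model_predict(params, grid)
    if noise_sd > 0:
        values = values + _rng(seed).normal(0.0, noise_sd, size=grid.size)
    return pd.Series(values, index=grid, name="wps")


def simulate_methylation(atlas: pd.DataFrame, true_proportions, noise_sd: float, seed: int) -> pd.Series:
    """Region methylation vector = atlas @ proportions + clipped Gaussian noise.

    ``true_proportions`` must lie on the simplex over the atlas cell types
    (tolerance 1e-6). Output values are clipped to [0, 1].
    """
    w = pd.Series(true_proportions, dtype=float).reindex(atlas.columns)
    if w.isna().any():
        raise ValueError("true_proportions must cover every atlas cell type")
    if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("true_proportions must lie on the simplex (sum to 1, nonnegative)")
    values = atlas.to_numpy(dtype=float) @ w.to_numpy()
    if noise_sd > 0:
        values = values + _rng(seed).normal(0.0, noise_sd, size=values.size)
    return pd.Series(np.clip(values, 0.0, 1.0), index=atlas.index, name="methylation")


def simulate_taxa(
    n_samples: int,
    contaminant_profile,
    planted: list[tuple] = (),
    total_reads: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genus-level read counts: multinomial contaminant background + planted signal.

    ``contaminant_profile`` maps genus -> background proportion (normalised
    internally); ``planted`` holds (sample_index, genus, abundance) triples
    with abundance in (0, 1): that fraction of the sample's non-human reads
    is assigned to the genus, the rest drawn from the background.

    Returns (counts: samples x genera DataFrame, totals: reads per sample).
    """
    profile = pd.Series(contaminant_profile, dtype=float)
    profile = profile / profile.sum()
    planted_by_sample: dict[int, list[tuple[str, float]]] = {}
    for sample_i, genus, ab in planted:
        if not 0 < ab < 1:
            raise ValueError(f"planted abundance must be in (0, 1), got {ab}")
        planted_by_sample.setdefault(int(sample_i), []).append((genus, float(ab)))
    genera = list(profile.index)
    for entries in planted_by_sample.values():
        for genus, _ in entries:
            if genus not in genera:
                genera.append(genus)
    rng = _rng(seed)
    counts = pd.DataFrame(0, index=[f"sample{i:03d}" for i in range(n_samples)], columns=genera, dtype=np.int64)
    for i in range(n_samples):
        planted_here = planted_by_sample.get(i, [])
        n_planted = 0
        for genus, ab in planted_here:
            c = int(round(ab * total_reads))
            counts.iloc[i, counts.columns.get_loc(genus)] += c
            n_planted += c
        n_bg = total_reads - n_planted
        if n_bg < 0:
            raise ValueError("planted abundances exceed the per-sample read total")
        bg = rng.multinomial(n_bg, profile.to_numpy())
        counts.loc[counts.index[i], profile.index] += bg
    totals = pd.Series(total_reads, index=counts.index, name="total_nonhuman_reads")
    return counts, totals


def simulate_reference_atlas(
    n_cell_types: int = 8,
    n_regions: int = 400,
    n_markers: int = 20,
    background: float = 0.85,
    marker_value: float = 0.05,
    background_sd: float = 0.03,
    seed: int = 0,
    prefix: str = "ct",
) -> pd.DataFrame:
    """Synthetic region x cell-type methylation atlas.

    Each cell type receives ``n_markers`` private hypomethylated marker
    regions (value ``marker_value``) on a hypermethylated background
    (``background`` with a small perturbation), emulating the hypo/hyper
    structure of real methylomes. Requires n_regions >= n_cell_types *
    n_markers.
    """
    if n_regions < n_cell_types * n_markers:
        raise ValueError("not enough regions for the requested private markers")
    rng = _rng(seed)
    values = np.clip(rng.normal(background, background_sd, size=(n_regions, n_cell_types)), 0.0, 1.0)
    for c in range(n_cell_types):
        rows = slice(c * n_markers, (c + 1) * n_markers)
        values[rows, c] = marker_value
    return pd.DataFrame(
        values,
        index=[f"region{r:05d}" for r in range(n_regions)],
        columns=[f"{prefix}{c}" for c in range(n_cell_types)],
    )
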