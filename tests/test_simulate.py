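"""Synthetic-data generators: determinism, composition, phasing structure."""

import numpy as np
import pandas as pd
import pytest

from cfphase.end_motifs import expected_motif_frequencies
from cfphase.oscillator import OscillatorParams, model_predict
from cfphase.simulate import (
    SimConfig,
    generate_genes,
    generate_genome,
    simulate_fragments,
    simulate_methylation,
    simulate_reference_atlas,
    simulate_wps_direct,
)


class TestGenerateGenome:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=5, genome_length=20_000)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_degenerate_gc_one(self):
        genome = generate_genome(SimConfig(seed=1, genome_length=10_000, gc_content=1.0))
        assert set(genome) <= {"G", "C"}

    def test_gc_concentration_at_1mb(self):
        genome = generate_genome(SimConfig(seed=2, genome_length=1_000_000, gc_content=0.5))
        gc = (genome.count("G") + genome.count("C")) / len(genome)
        assert 0.48 <= gc <= 0.52

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(SimConfig(seed=0, genome_length=500))


class TestGenerateGenes:
    def test_zero_genes(self):
        cfg = SimConfig(seed=0, genome_length=20_000, n_genes=0)
        assert len(generate_genes(cfg, generate_genome(cfg))) == 0

    def test_flank_and_spacing_constraints(self):
        cfg = SimConfig(seed=3, genome_length=150_000, n_genes=15)
        genome = generate_genome(cfg)
        genes = generate_genes(cfg, genome)
        assert len(genes) == 15
        tss = genes["tss"].to_numpy()
        assert (tss >= 2500).all() and (tss <= len(genome) - 2500).all()
        # exhaustive pairwise spacing check
        for i in range(len(tss)):
            for j in range(i + 1, len(tss)):
                assert abs(int(tss[i]) - int(tss[j])) >= 6000

    def test_genome_too_short_for_genes(self):
        cfg = SimConfig(seed=0, genome_length=20_000, n_genes=10)
        with pytest.raises(ValueError):
            generate_genes(cfg, generate_genome(cfg))

    def test_activity_split(self):
        cfg = SimConfig(seed=4, genome_length=200_000, n_genes=20, active_fraction=0.5)
        genes = generate_genes(cfg, generate_genome(cfg))
        assert (genes["activity"] == "active").sum() == 10


class TestSimulateFragments:
    def test_empty_when_nothing_configured(self):
        cfg = SimConfig(seed=0, genome_length=50_000, n_genes=2, fragments_per_nucleosome=0, background_rate=0.0)
        genome = generate_genome(cfg)
        genes = generate_genes(cfg, genome)
        assert len(simulate_fragments(cfg, genes, genome)) == 0

    def test_seed_determinism(self):
        cfg = SimConfig(seed=8, genome_length=60_000, n_genes=3)
        genome = generate_genome(cfg)
        genes = generate_genes(cfg, genome)
        pd.testing.assert_frame_equal(simulate_fragments(cfg, genes, genome), simulate_fragments(cfg, genes, genome))

    def test_degenerate_mono_mixture(self):
        cfg = SimConfig(
            seed=1,
            genome_length=100_000,
            n_genes=0,
            background_rate=0.1,  # ~1e4 background fragments
            class_mix={"sub": 0.0, "mono": 1.0, "di": 0.0, "poly": 0.0},
        )
        genome = generate_genome(cfg)
        frags = simulate_fragments(cfg, generate_genes(cfg, genome), genome)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        assert len(frags) > 5000
        assert lengths.min() >= 120 and lengths.max() <= 250

    def test_class_mix_within_multinomial_ci(self):
        mix = {"sub": 0.1, "mono": 0.6, "di": 0.2, "poly": 0.1}
        cfg = SimConfig(seed=2, genome_length=200_000, n_genes=0, background_rate=0.05, class_mix=mix)
        genome = generate_genome(cfg)
        frags = simulate_fragments(cfg, generate_genes(cfg, genome), genome)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        n = len(lengths)
        observed = {
            "sub": np.mean(lengths < 120),
            "mono": np.mean((lengths >= 120) & (lengths <= 250)),
            "di": np.mean((lengths >= 251) & (lengths <= 420)),
            "poly": np.mean(lengths > 420),
        }
        for cls, p in mix.items():
            half_width = 2.576 * np.sqrt(p * (1 - p) / n)  # 99% CI
            assert abs(observed[cls] - p) <= half_width + 0.01

    def test_jitter_sd_grows_with_nucleosome_index(self):
        cfg = SimConfig(
            seed=3,
            genome_length=60_000,
            n_genes=1,
            active_fraction=1.0,
            fragments_per_nucleosome=1000,
            background_rate=0.0,
            jitter_base_sd=3.0,
            jitter_growth_sd=3.0,
            cc_end_bias=1.0,
        )
        genome = generate_genome(cfg)
        genes = generate_genes(cfg, genome)
        frags = simulate_fragments(cfg, genes, genome)
        tss = int(genes["tss"].iloc[0])
        sign = 1 if genes["strand"].iloc[0] == "+" else -1
        centres = (frags["start"] + frags["end"]).to_numpy() / 2
        sds = []
        for n in range(cfg.n_nucleosomes):
            nominal = tss + sign * (100 + n * cfg.nucleosome_repeat)
            mine = centres[np.abs(centres - nominal) < cfg.nucleosome_repeat / 2]
            sds.append(mine.std())
        assert all(np.diff(sds) > 0)

    def test_cc_bias_enriches_cc_starts(self):
        base = dict(seed=4, genome_length=100_000, n_genes=0, background_rate=0.1)
        genome = generate_genome(SimConfig(**base))

        def cc_fraction(bias):
            cfg = SimConfig(**base, cc_end_bias=bias)
            frags = simulate_fragments(cfg, generate_genes(cfg, genome), genome)
            starts = frags["start"].to_numpy()
            return np.mean([genome[s : s + 2] == "CC" for s in starts])

        expected = expected_motif_frequencies(genome)
        cc_expected = expected[expected.index.str.startswith("CC")].sum()
        assert cc_fraction(4.0) > cc_expected
        assert cc_fraction(4.0) > cc_fraction(1.0)


class TestSimulateWpsDirect:
    PARAMS = OscillatorParams(kappa=0.002, A=0.5, lam=0.001, omega=2 * np.pi / 187, phi=0.3, b=0.0)

    def test_noiseless_equals_model(self):
        grid = np.arange(-500, 500)
        prof = simulate_wps_direct(self.PARAMS, grid, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(prof.to_numpy(), model_predict(self.PARAMS, grid))

    def test_flat_params_give_constant_one(self):
        p = OscillatorParams(kappa=0.0, A=0.0, lam=0.0, omega=0.1, phi=0.0, b=0.0)
        prof = simulate_wps_direct(p, np.arange(-100, 100), noise_sd=0.0, seed=0)
        assert np.allclose(prof, 1.0)

    def test_noise_sd_within_chi_square_bounds(self):
        grid = np.arange(-1000, 1000)
        prof = simulate_wps_direct(self.PARAMS, grid, noise_sd=0.05, seed=42)
        resid = prof.to_numpy() - model_predict(self.PARAMS, grid)
        assert 0.045 <= resid.std(ddof=1) <= 0.055

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_wps_direct(self.PARAMS, np.arange(-3000, 0), 0.0, 0)


class TestSimulateMethylation:
    def test_pure_cell_type_equals_atlas_column(self):
        atlas = simulate_reference_atlas(n_cell_types=3, n_regions=120, seed=0)
        sample = simulate_methylation(atlas, {"ct0": 1.0, "ct1": 0.0, "ct2": 0.0}, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(sample.to_numpy(), atlas["ct0"].to_numpy())

    def test_even_mixture_is_midpoint(self):
        atlas = simulate_reference_atlas(n_cell_types=2, n_regions=80, seed=1)
        sample = simulate_methylation(atlas, {"ct0": 0.5, "ct1": 0.5}, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(sample.to_numpy(), atlas.mean(axis=1).to_numpy())

    def test_values_clipped_to_unit_interval(self):
        atlas = simulate_reference_atlas(n_cell_types=2, n_regions=80, seed=2)
        sample = simulate_methylation(atlas, {"ct0": 0.5, "ct1": 0.5}, noise_sd=0.5, seed=3)
        assert sample.between(0.0, 1.0).all()

    def test_off_simplex_rejected(self):
        atlas = simulate_reference_atlas(n_cell_types=2, n_regions=80, seed=0)
        with pytest.raises(ValueError):
            simulate_methylation(atlas, {"ct0": 0.7, "ct1": 0.7}, noise_sd=0.0, seed=0)
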