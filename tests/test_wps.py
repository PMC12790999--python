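"""Windowed protection score: counting rules, smoothing, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from cfphase.simulate import SimConfig, generate_genes, generate_genome, simulate_fragments
from cfphase.wps import (
    TssRegion,
    adjust_and_smooth,
    aggregate_gene_set,
    compute_gene_profile,
    compute_gene_profiles,
    filter_mononucleosomal,
    gaussian_smooth,
    raw_wps,
)

from conftest import wps_bruteforce


def _frags(intervals):
    return pd.DataFrame([("chr1", s, e) for s, e in intervals], columns=["chrom", "start", "end"])


class TestMononucleosomalFilter:
    def test_inclusive_bounds(self):
        frags = _frags([(0, 119), (0, 120), (0, 200), (0, 201)])
        kept = filter_mononucleosomal(frags)
        assert sorted(kept["end"] - kept["start"]) == [120, 200]

    def test_empty_in_empty_out(self):
        assert len(filter_mononucleosomal(_frags([]))) == 0

    def test_count_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(50, 400, size=500)
        frags = _frags([(0, int(L)) for L in lengths])
        expected = sum(1 for L in lengths if 120 <= L <= 200)
        assert len(filter_mononucleosomal(frags)) == expected


class TestRawWps:
    def test_no_fragments_all_zero(self):
        assert (raw_wps(np.array([]), np.array([]), 0, 300) == 0).all()

    def test_single_fragment_hand_scores(self):
        # 167-bp fragment centred at p: window [p-60, p+60) is fully inside
        # the fragment (+1); a window containing the start but not spanned
        # scores -1
        s, e = 1000, 1167
        centre = (s + e) // 2
        scores = raw_wps(np.array([s]), np.array([e]), 900, 1300)
        assert scores[centre - 900] == 1
        assert scores[s + 10 - 900] == -1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            span_start = int(rng.integers(0, 500))
            span_end = span_start + 250
            n = int(rng.integers(1, 40))
            starts = rng.integers(span_start - 300, span_end + 300, size=n)
            ends = starts + rng.integers(1, 260, size=n)
            fast = raw_wps(starts, ends, span_start, span_end)
            slow = wps_bruteforce(starts, ends, span_start, span_end)
            np.testing.assert_array_equal(fast, slow)

    def test_boundary_tie_rule(self):
        # fragment start exactly at window start counts as spanning-
        # compatible, not as an interior endpoint
        p = 200
        s, e = p - 60, p + 200  # at position p: s == W.start, e > W.end
        scores = raw_wps(np.array([s]), np.array([e]), p - 60, p + 60)
        assert scores[60] == 1
        # ...and a fragment ending exactly at W.start is entirely outside
        scores = raw_wps(np.array([s - 100]), np.array([p - 60]), p - 60, p + 60)
        assert scores[60] == 0

    def test_additivity(self):
        rng = np.random.default_rng(2)
        sa = rng.integers(0, 400, size=25)
        ea = sa + rng.integers(1, 250, size=25)
        sb = rng.integers(0, 400, size=30)
        eb = sb + rng.integers(1, 250, size=30)
        union = raw_wps(np.concatenate([sa, sb]), np.concatenate([ea, eb]), 0, 400)
        np.testing.assert_array_equal(union, raw_wps(sa, ea, 0, 400) + raw_wps(sb, eb, 0, 400))

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        s = rng.integers(0, 400, size=20)
        e = s + rng.integers(1, 250, size=20)
        shift = 1234
        np.testing.assert_array_equal(
            raw_wps(s, e, 0, 400), raw_wps(s + shift, e + shift, shift, 400 + shift)
        )

    def test_window_larger_than_span_is_error(self):
        with pytest.raises(ValueError):
            raw_wps(np.array([0]), np.array([200]), 0, 100, window=120)


class TestAdjustAndSmooth:
    def test_constant_profile_maps_to_zero(self):
        adjusted, smoothed = adjust_and_smooth(np.full(5000, 7.0))
        assert np.allclose(adjusted, 0.0)
        assert np.allclose(smoothed, 0.0)

    def test_adjusted_has_zero_mean(self):
        rng = np.random.default_rng(0)
        adjusted, _ = adjust_and_smooth(rng.integers(-5, 6, size=5000).astype(float))
        assert abs(adjusted.mean()) < 1e-9

    def test_impulse_response_is_discrete_gaussian(self):
        impulse = np.zeros(5001)
        impulse[2500] = 1.0
        smoothed = gaussian_smooth(impulse, bandwidth=30)
        assert smoothed[2500] == pytest.approx(1 / (np.sqrt(2 * np.pi) * 30), abs=1e-6)

    def test_smoothing_preserves_zero_sum_away_from_edges(self):
        # the kernel has unit mass, so a zero-sum signal supported well
        # inside the span smooths to a zero-sum signal
        signal = np.zeros(5000)
        signal[2000], signal[3000] = 1.0, -1.0
        smoothed = gaussian_smooth(signal, bandwidth=30)
        assert abs(smoothed.sum()) < 1e-9

    def test_edge_renormalisation_keeps_constants_constant(self):
        smoothed = gaussian_smooth(np.full(400, 3.0))
        assert np.allclose(smoothed, 3.0)


class TestAggregation:
    def test_identical_profiles_zero_ci_width(self):
        cfg = SimConfig(seed=1, genome_length=60_000, n_genes=2, active_fraction=1.0, background_rate=0.01)
        genome = generate_genome(cfg)
        genes = generate_genes(cfg, genome)
        frags = simulate_fragments(cfg, genes, genome)
        region = TssRegion("g", "chr1", int(genes["tss"].iloc[0]), "+")
        prof = compute_gene_profile(frags, region)
        agg = aggregate_gene_set([prof, prof, prof])
        np.testing.assert_allclose(agg.mean, prof.smoothed)
        np.testing.assert_allclose(agg.ci_high - agg.ci_low, 0.0, atol=1e-12)

    def test_minus_strand_mirroring_is_involution(self):
        frags = _frags([(900, 1060), (1200, 1360)])
        plus = compute_gene_profile(frags, TssRegion("g", "chr1", 1100, "+"))
        minus = compute_gene_profile(frags, TssRegion("g", "chr1", 1100, "-"))
        np.testing.assert_array_equal(minus.raw[::-1], plus.raw)
        # mirroring twice recovers the original orientation
        np.testing.assert_array_equal(minus.raw[::-1][::-1], minus.raw)

    def test_empty_gene_set_is_error(self):
        with pytest.raises(ValueError):
            aggregate_gene_set([])


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(
        seed=5,
        genome_length=1_300_000,
        n_genes=200,
        active_fraction=0.5,
        nucleosome_repeat=187,
        background_rate=0.002,
    )
    genome = generate_genome(cfg)
    genes = generate_genes(cfg, genome)
    frags = simulate_fragments(cfg, genes, genome)
    return cfg, genes, frags


class TestPhasedSignal:
    def test_aggregate_peaks_at_nucleosome_positions(self, cohort):
        cfg, genes, frags = cohort
        active = genes.loc[genes["activity"] == "active"]
        agg = aggregate_gene_set(compute_gene_profiles(frags, active))
        downstream = (agg.distances >= 0) & (agg.distances <= 1100)
        peaks, _ = find_peaks(agg.mean[downstream], distance=100)
        peak_d = agg.distances[downstream][peaks]
        expected = 100 + 187 * np.arange(5)
        for target in expected:
            assert np.min(np.abs(peak_d - target)) <= 15

    def test_inactive_genes_show_no_phasing(self, cohort):
        cfg, genes, frags = cohort

        def periodic_strength(agg):
            x = agg.mean - agg.mean.mean()
            lags = np.arange(150, 251)
            ac = [np.corrcoef(x[:-lag], x[lag:])[0, 1] for lag in lags]
            return np.max(np.abs(ac))

        active = aggregate_gene_set(compute_gene_profiles(frags, genes.loc[genes["activity"] == "active"]))
        inactive = aggregate_gene_set(
            compute_gene_profiles(frags, genes.loc[genes["activity"] == "inactive"], drop_empty=False)
        )
        assert periodic_strength(inactive) < periodic_strength(active)
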