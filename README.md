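# cfphase

A toolkit for the analytical layer of plasma cell-free DNA (cfDNA)
"circulome" studies: fragment-length statistics and fragmentation indices,
oriented fragment end-motif analysis, windowed-protection-score (WPS)
nucleosome footprinting with a damped-harmonic-oscillator model of
nucleosome phasing, hierarchical methylome deconvolution with
genome-equivalents / cellular-turnover estimation, and microbial-abundance
outlier detection. A synthetic-data module generates every input the
analyses consume, so the whole pipeline is exercisable without
controlled-access patient data.

## Who it is for

cfDNA is released into plasma by dying cells and cleared within hours,
which makes it a real-time readout of cell death, gene activity and
clearance physiology — of particular interest in acute conditions such as
sepsis. This package implements the downstream computations such a study
needs once reads have been aligned: it consumes fragment coordinate tables
(BED3/TSV), a genome FASTA, a TSS annotation, region-level methylation
matrices with reference atlases, and genus-level read-count tables.

## The core model

The aggregated WPS signal around the transcription start sites of active
genes shows a dip at the promoter nucleosome-free region followed by
periodic oscillations from phased nucleosomes. `cfphase` models this as an
exponential trend plus a damped harmonic oscillator:

    WPS(d) = e^(−κd) + A · e^(−λd) · cos(ωd − φ) + b

with d the signed distance from the TSS (bp), κ the trend decay constant
(1/bp), A the oscillation amplitude, λ the amplitude decay rate (how fast
phasing is lost with distance), ω the angular frequency (the nucleosome
repeat length is the period 2π/ω), φ the phase displacement and b an
offset. Fitting uses nonlinear least squares in two stages (trend first,
oscillator on the residuals, multi-start over φ) followed by a joint
polish, restricted to d ∈ [−185, 925] bp — the NFR plus the first five
downstream nucleosomes. The API follows the statsmodels Model/Results
idiom:

```python
from cfphase import PhasingOscillatorModel

res = PhasingOscillatorModel(profile).fit()
print(res.summary())          # coefficients, RMSE, derived period
res.params.period             # nucleosome repeat length, bp
```

Other headline definitions (all exposed as configurable defaults):
size classes sub <120 / mono 120–250 / di 251–420 / poly >420 bp;
fragmentation index FI = count(length=167) / count(length=334);
mononucleosomal WPS filter 120–200 bp; 120-bp centred sliding window;
30-bp Gaussian smoothing; genome equivalents GEQ/ml = pᵢ · purity ·
yield / 0.006 ng; microbial detection floor of 10 reads and outlier rule
mean + 3.5 SD of the pooled abundance distribution.

## Worked example

The end-to-end synthetic demonstration builds a cohort of 10 "patients"
(strong phasing, CC cleavage bias, high mono:di ratio, a planted
pathogen) and 5 "controls", then runs every module:

```
$ cfphase demo --outdir demo_out --seed 0
[ok] fi_higher_in_high_mono_group
[ok] cc_motifs_enriched_in_patients
[ok] period_within_5bp_of_repeat
[ok] deconvolution_mae_below_0.05
[ok] planted_pathogen_flagged
fi_wilcoxon_p = 0.000666001
median_period_bp = 187.612
deconvolution_mae = 0.0036642
```

Patient fragmentation indices (26–57) separate cleanly from controls
(10–12; Wilcoxon p = 0.0007) because patients were simulated with a
larger mononucleosome fraction; the median fitted oscillation period of
187.6 bp recovers the 187-bp nucleosome repeat used by the generator; and
hierarchical deconvolution recovers the simulated cell-type mixtures with
a mean absolute error of 0.004. `demo_out/` holds the per-sample tables,
the WPS profile and volcano figures, and a `report.json` with these
numbers. The same pieces are available as library functions and as
focused subcommands (`simulate`, `fraglen`, `endmotifs`, `wps`, `oscfit`,
`deconv`, `turnover`, `microbes`).

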