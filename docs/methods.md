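# Methods

This note documents the models and procedures implemented in `cfphase`,
the parameters that matter, the synthetic-data generator's assumptions,
and the design choices made where the underlying methodology left the
design open.

## Fragmentomics

A fragment is a genomic interval (0-based, half-open); its length is
`end − start`. Length histograms are exact tallies. Size classes use the
operational boundaries sub < 120 bp, mono 120–250 bp, di 251–420 bp,
poly > 420 bp (inclusive bounds as written); descriptive prose in the
field sometimes uses mono 120–220 / di 220–420 for the same data, so the
boundaries are exposed as a parameter. The fragmentation index is the
ratio of raw counts at exactly 167 bp and 334 bp — the mono- and
dinucleosomal peak positions — not of counts within ranges. An optional
*peak mode* instead takes the modal count within each class range, which
is the right choice for shallow data where the exact-334 count can be
zero (the demo uses it for this reason); the strict definition is the
default. Duplicate fragments are counted, not collapsed — duplicate
marking belongs upstream. Group contrasts report both the Welch t-test
and the two-sided Wilcoxon rank-sum test (exact null when sample sizes
and ties permit); groups are ordered by sorted label so relabelling flips
the sign of the contrast and nothing else.

## End motifs

Both termini of a fragment are nuclease cut sites. The upstream motif is
the first k = 4 reference bases of the fragment; the downstream motif is
the reverse complement of the last k reference bases, because that end's
5′→3′ sequence lies on the minus strand. Both ends are pooled into one
frequency table per sample (per-end tables are available); motifs
containing N, or ends out of genome bounds, are skipped and counted, and
frequencies are normalised over counted motifs. Expected frequencies are
exact sliding-window k-mer counts over the genome **and its reverse
complement** — fragment ends sample both strands, so the baseline must
too (forward-only counting is a flag). N-containing windows are excluded.
Differential usage is a per-motif two-sided Wilcoxon test with BH
correction across the 256 motifs; log₂ fold changes guard against zeros
with a pseudo-frequency of half the smallest nonzero table entry.
Covariate screens use Pearson correlation with pairwise deletion of
missing values and BH correction.

## WPS nucleosome footprinting

Only mononucleosomal fragments (120 ≤ length ≤ 200 bp, both inclusive)
carry clean single-nucleosome protection information and enter the WPS.
For each position p of the 5-kb span centred on a TSS, the window
W(p) = [p−60, p+60) is scored as (+1 per fragment fully spanning W) minus
(1 per fragment with at least one endpoint strictly inside W, however
many endpoints are inside). Tie rule: an endpoint exactly on a window
boundary is not "inside"; a fragment starting at W.start therefore counts
toward spanning, not against it. The window is centred on the evaluated
position (the anchor is configurable). The implementation uses difference
arrays in O(F + P); the test-suite keeps an O(F × P) enumeration oracle
and requires exact integer agreement.

Raw profiles are coverage-adjusted by subtracting the span mean
(per gene, per 5-kb region, before any aggregation) and smoothed with a
discrete Gaussian kernel of SD 30 bp, truncated at ±4 SD and renormalised;
at the span edges the kernel is renormalised over the available support,
so constants are preserved exactly. Minus-strand profiles are mirrored so
positive distances run downstream in the transcription direction.
Gene-set aggregation averages per-gene smoothed profiles (not
pooled-fragment WPS — the confidence band is defined *across genes*):
mean ± 1.96·SE per position. Genes with zero overlapping fragments are
dropped and `n_genes` records how many contributed.

## Nucleosome phasing model

The aggregate WPS is modelled as
`WPS(d) = e^(−κd) + A·e^(−λd)·cos(ωd − φ) + b` on d ∈ [−185, 925] bp,
which covers the promoter NFR and the first five downstream nucleosomes.
The first term has no amplitude coefficient by construction; at d < 0 it
rises above 1 and, together with b, absorbs the NFR dip. Interpretation:
κ and A describe footprint strength at the TSS, λ the decay of phasing
with distance, ω and φ the nucleosome repeat geometry (period = 2π/ω).

Fitting is nonlinear least squares in two stages to aid convergence: the
trend `e^(−κd) + b` is fitted first (b belongs to the trend as its
asymptote), then the oscillator is fitted to the stage-1 residuals with a
multi-start over φ₀ ∈ {0, π/2, π, 3π/2} (ω₀ = 2π/185, λ₀ = 10⁻³,
A₀ = max|residual|; best RMSE wins, ties broken by smaller λ). Because
stage 1 unavoidably leaks a little oscillation into the trend, a final
joint least-squares polish over all six coefficients starts from the
staged estimates and is kept only if it lowers the RMSE; `refine=False`
gives the bare staged fit. Bounds keep the fit biophysically meaningful:
period ∈ [80, 400] bp, κ, λ ∈ [0, 0.1] /bp, |A| ≤ 10 × profile range.
A is sign-normalised to A ≥ 0 (φ ← φ+π), φ wrapped to [0, 2π).
Optimiser failure is reported as `converged=False`, never an exception.
Tolerances: 10⁻⁸ relative on the staged objectives, 10⁴ evaluation cap.

Cohort summaries: coefficients of variation (SD/|mean|) are computed over
converged fits only, with CV undefined (NaN) when a parameter's mean is
zero; the derived period is summarised alongside ω. Parameter–covariate
screens use Pearson correlation with BH adjustment, excluding
non-converged fits pairwise.

## Deconvolution, genome equivalents, turnover

Cell-type proportions are estimated by nonnegative least squares of the
sample's region-methylation vector on a reference atlas, optionally
robustified by iteratively-reweighted Huber weights (δ = 1.345 × MAD
scale), then renormalised to the simplex. This matches the contract of
robust-partial-correlation (RPC) reference-based deconvolution without
reproducing any particular implementation bit-for-bit; recovery is
validated on synthetic mixtures instead. Atlas/sample region mismatches
are resolved by intersection (dropped regions logged); missing sample
values are dropped pairwise; near-rank-deficient atlases are flagged with
the condition number.

The hierarchical variant extends a solid-tissue atlas with one
"immune cells" column — the immune atlas averaged with each immune cell
type weighted by its proportion in whole blood, weights normalised to
sum 1 — and deconvolves in two steps. Design choices where the procedure
was open: (1) estimates are simplex-normalised at both steps; (2) the
step-2 split of the immune fraction runs on the sample **minus the
step-1 solid-tissue component**. Running step 2 on the raw sample lets
solid-tissue background methylation masquerade as whichever immune type
has no marker signal in the sample; subtracting the estimated tissue
component removes that failure mode and makes noiseless mixtures recover
exactly. The whole-blood weights are a user input; the method implicitly
assumes the sample's immune composition resembles them, and recovery
degrades gracefully as they diverge.

Genome equivalents convert proportions to absolute genomes per ml:
GEQ/ml = pᵢ · purity · yield / 0.006, with 0.006 ng the average DNA mass
of one diploid genome, purity the fraction of the DNA yield that is true
cfDNA, and yield in ng per ml plasma. Turnover is GEQ/ml divided by the
matching CBC live-cell count per ml; a ratio of 1 marks cell death and
production in balance.

## Microbial DNA

Genus read counts are converted to abundances as reads divided by the
sample's total non-human reads; genera below 10 reads in a sample are
non-detections (NaN), and the denominator is *not* recomputed after
filtering. The outlier filter pools every detected (sample, genus)
abundance in the cohort into one distribution — one distribution, one
cutoff — and flags entries at least k = 3.5 SD above the pooled mean;
the rule operates on raw abundances by default with a log-scale flag.
Non-detections are excluded from the pool (they are absences, not low
signals) but enter group tests as abundance 0, because absence is
informative there. Differential abundance uses per-genus Wilcoxon tests
with BH correction, chosen for consistency with the package's other
nonparametric contrasts. Culture concordance is a two-sided Fisher exact
test on the flagged-vs-background × confirmed-vs-not 2×2 table, with a
Haldane 0.5 correction of the odds ratio when a cell is zero.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not sequencing itself (no reads, no error model, no conversion
chemistry):

* **Genome** — i.i.d. bases at a configurable GC content (default 0.41,
  human-like), single chromosome by default since nothing downstream
  depends on chromosome count.
* **Genes** — TSSs ≥ 2.5 kb from the ends and ≥ 6 kb apart (so 5-kb
  footprinting spans never overlap), strands ~50/50, a configurable
  fraction labelled active.
* **Fragments** — for each active gene, nucleosomes n = 0..9 sit at
  TSS + strand·(100 + n·R) with repeat R = 187 bp by default; the +100 bp
  first-nucleosome offset is a stand-in for the NFR width. Each of the
  `fragments_per_nucleosome` fragments re-draws its centre with jitter
  SD = 5 + 2n bp (one fragment = one cell), so phasing decays with
  nucleosome index; this jitter-growth mechanism is a modelling stand-in
  for phasing decay and is not calibrated to any cohort. Fragment lengths
  are ⌈N(167, 5)⌉. Background fragments arrive as a Poisson process over
  the genome with lengths drawn from the size-class mixture
  (defaults mono 90.75%, di 5.2%, poly 0.61%, remainder subnucleosomal —
  cohort-typical proportions); inactive genes receive background only and
  serve as the random-arrangement control. An optional CC cleavage bias
  resamples fragments with odds multiplied by `cc_end_bias` when the
  reference 5′ 2-mer is CC (count-preserving weighted resampling).
* **Methylation** — atlas × proportions plus clipped Gaussian noise; the
  synthetic atlas gives each cell type 20 private hypomethylated marker
  regions (0.05) on a ~0.85 hypermethylated background. When tests need a
  tissue and an immune reference they split one combined atlas so marker
  regions stay disjoint.
* **Taxa** — multinomial contaminant background plus planted
  (sample, genus, abundance) signals at fixed per-sample totals.

Every generator is a pure function of (config, seed). Because the
generator is idealised — no GC coverage bias, no mappability structure,
no duplicate fragments, no batch effects — passing tests demonstrate the
*correctness of the computations and the identifiability of the models
under their own assumptions*, not performance on real plasma data.

## Problem sizes and numerics

The direct-model recovery uses 21 profiles on a 1-bp grid over
[−185, 925] with noise SD 0.05; the fragment-level recovery uses 500
active genes × 10 nucleosomes × 50 fragments (250k fragments) on a 3.2-Mb
genome — sizes at which the fitted period is stable to ~1 bp while the
full pipeline runs in seconds. Degenerate inputs are defined errors, not
crashes: empty histograms, a zero 334-bp count (undefined FI carrying its
numerator), off-simplex mixture inputs, zero-variance covariates, empty
Fisher margins, zero-variance outlier pools (no flags).

## Known limitations

* The WPS window anchor, kernel edge handling (truncated-renormalised
  rather than reflected) and per-gene-then-average aggregation are
  documented choices among defensible alternatives; all are configurable.
* The oscillator's trend term grows above 1 for d < 0 as written; the fit
  region starts at −185 bp so this is bounded, but κ and b should not be
  interpreted in isolation upstream of the TSS.
* Deconvolution accuracy depends on marker quality and on the whole-blood
  weights; the package reports condition numbers but does not attempt
  atlas curation.
* The microbial module consumes classified counts; classification quality
  and contaminant curation are out of scope.
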