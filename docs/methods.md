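# Methods

This note documents the models and numerical choices behind `leaftracer`,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Isotope labelling model

A compound with *n* nitrogen atoms measured over isotopologues M+0..M+x_max
(x_max = 4 by default, matching a typical SIR acquisition) is summarised by
its mass-isotopologue distribution (MID). Fractional labelling is the plain
normalisation `f(x) = I(x) / Σ I(y)`; it is only defined when the vector
carries signal, and an all-zero vector raises a degenerate-input error that
names the sample and compound.

**Derivatisation artifact.** AccQTag derivatisation shifts a fraction
*r* ≈ 0.2 of each isotopologue's signal up one mass unit. We model this as a
shift convolution, `observed(x) = (1−r)·true(x) + r·true(x−1)`, and invert it
exactly with the recursion `true(0) = observed(0)/(1−r)`,
`true(x) = (observed(x) − r·true(x−1))/(1−r)`. The inversion is exact even
when the acquisition window truncates the shifted tail, because
`observed(0..x)` depends only on `true(0..x)`. A naive mode
(`subtract_standard`: move the fraction r of total signal from M+1 back to
M+0) is kept behind a switch for sensitivity checks; it coincides with the
deconvolution when only M+0/M+1 are populated.

*r* is estimated per analytical batch as the mean M+1 fraction of ¹⁵N-free
external standards in excess of a configurable baseline. The default
baseline is zero: the standard's own natural-abundance M+1 is deliberately
left inside *r*, because the net-labelling step subtracts the experiment's T0
baseline anyway and the two conventions cancel. A theoretical baseline
(0.003663 per N atom) is available for workflows without T0 samples.

**Truncation to the nitrogen count.** After artifact removal, isotopologues
above *n* (e.g. M+2..M+4 for proline) cannot carry ¹⁵N and contain only
deconvolution-amplified noise; the per-replicate standard deviation of a
deconvolved trace isotopologue is of order `cv·r·√2/(1−r)` of total signal,
and clipping its negative excursions to zero would bias baselines upward.
The experiment model therefore truncates each corrected MID to `n+1` entries
before normalising. This is the one place the analysis uses compound
identity; unknown compounds are kept at full length.

**Net labelling and allocation.** `net(x) = f_sample(x) − f_T0(x)` with the
T0 baseline averaged over all T0 replicates of the batch (natural abundance
does not depend on leaf rank). Net values sum to zero by construction (a
uniform float residue is removed) and may legitimately be negative at M+0.
The mean number of labelled atoms per molecule is `Σ x·net(x)`, bounded by
±n, and net ¹⁵N allocation is `content × mean labelled atoms × 1000` in
nmol ¹⁵N g⁻¹ DW per labelling period. Rate conversion to h⁻¹ is left to the
reporting layer. Protein-bound ¹⁵N is ignored (below detection in the
leaf-disc assays this mirrors).

## Quantification

External calibration is an OLS line of area vs concentration (≥3 distinct
standards); inversion outside the fitted range warns rather than errors,
because small leaf-disc pools can fall below the lowest standard. The
internal standard (dl-3-aminobutyric acid, 111 µM in the 0.9 ml MeOH/H₂O
fraction) provides a per-sample recovery factor: areas are scaled by
(expected IS response / observed IS area). The volume chain — 0.9 ml
fraction, 200 µl aliquot evaporated, 50 µl resuspension — collapses to an
effective extract volume of 0.225 ml and is configurable. Contents clip at
zero (areas below the calibration intercept) with a logged warning.

## qPCR expression

Primer efficiency comes from the dilution-series slope (≥3 points over ≥2
log₁₀ units, slope necessarily negative), `E = 10^(−1/slope)`, accepted in
(1, 2.2]. Relative expression uses measured per-gene efficiencies throughout
(also for reference genes) and is computed in log space:
`RE = E_t^(−Cq_t) / geomean_j(E_j^(−Cq_j))`. Technical replicate Cq values
are averaged first; undetected wells are missing values, never Cq = 40, and
propagate as "not detected" rather than zero. A sample missing a reference
Cq is excluded with a warning. With equal efficiencies RE is exactly
invariant under uniform Cq shifts; with per-gene efficiencies a uniform
shift rescales all samples of a gene equally, leaving all within-gene
comparisons (FC, log₂ ratios) unchanged.

geNorm stability: `M_j` is the mean over other candidates of the SD
(ddof = 1) across samples of `log2(a_j/a_k)`, requiring ≥3 candidates and ≥2
samples; the iterative variant repeatedly removes the least stable gene
(ties broken alphabetically for determinism) and reports the exclusion
order. Candidates should be putative reference genes — condition-responsive
targets would dominate M by construction, so the pipeline restricts geNorm
to reference + decoy roles when role annotations are present.

Fold changes are ratios of (geometric-mean) relative expression between two
consecutive time points within each arm, and the headline summary is
log₂(FC_treatment/FC_control).

## Group statistics

One-way ANOVA (scipy) with Tukey HSD pairwise p-values (statsmodels) and a
compact letter display built by insert-and-absorb: start from one letter
covering all groups; for each significant pair split every letter containing
both members and absorb subsets. Letters are assigned in order of each
set's first group, so the labels are reproducible; only the sharing pattern
is meaningful. Two-condition comparisons use the pooled-variance two-sided
t-test; a zero-pooled-variance degenerate input returns p = 1 for equal
means and p = 0 otherwise. Expression values are natural-log transformed
before testing (the base does not affect decisions). α = 0.05 by default.

## Osmotic design

Ψ(C, T) in bars is the Michel & Kaufman (1973) empirical polynomial
(−1.18·10⁻² C − 1.18·10⁻⁴ C² + 2.67·10⁻⁴ CT + 8.39·10⁻⁷ C²T), converted to
MPa. Validity envelope C ∈ [0, 800] g kg⁻¹, T ∈ [5, 35] °C; outside it the
value is still computed with a warning. The incubation temperature of the
assays is not recorded; T = 20 °C is the default because it reproduces the
−1.88 MPa dose at 400 g kg⁻¹. The inverse solves Ψ(C) = Ψ_target by Brent's
method on the envelope to 10⁻⁶ g kg⁻¹ and reports the achievable range when
the target is out of reach.

## Synthetic-data generator

The generator is the package's stand-in for raw LC-MS and qPCR data and
defines the conditions all end-to-end tests run under.

* **Labelling**: each of the *n* nitrogen positions of a molecule is ¹⁵N
  independently with probability *p* — the realised per-atom incorporation
  after 4 h (tracer purity folded into *p*) — or the natural abundance
  p₀ = 0.003663 at T0. The binomial MID is forward-convolved with r = 0.20,
  scaled to intensities proportional to content (10⁵ counts per µmol g⁻¹),
  and multiplied by mean-one lognormal noise with CV = 0.02. Defaults:
  proline per-atom enrichment 0.10/0.07/0.02/0.005 across leaf ranks
  L15/L11/L7/L3 with contents 2.0/1.1/0.5/0.5 µmol g⁻¹ DW (so the L15
  allocation lands near 200 nmol ¹⁵N g⁻¹ DW), glutamate 0.54 everywhere,
  glutamine 0.72 per atom (giving M+1/M+2 fractions near the observed
  0.30–0.35/0.50–0.55 band; an independent-atom binomial cannot match both
  margins exactly). Standards are pure M+0 plus the artifact, without
  natural abundance, consistent with the baseline-zero convention above.
  n = 3 biological replicates.
* **qPCR**: `Cq = 25 − log_E(expression) + N(0, 0.2)`, duplicate wells,
  per-sample biological jitter lognormal in log₂ with SD 0.05 (reference and
  target genes) or 0.8 (the decoy gene, deliberately unstable for geNorm
  testing). The default design is the osmotic-shock contrast: control and
  treatment arms at T0/T1 with a log₂ FC ratio of 7 for the strongly induced
  biosynthesis gene, +2 and −2 for moderate cases. Dilution series are four
  decades, duplicate.
* **Quantification**: linear calibration (slope 100 area µM⁻¹) over
  5–500 µM, sample areas consistent with configured contents through the
  volume chain, shared per-sample IS recovery jitter (lognormal SD 0.05).

Same config and seed give byte-identical outputs (stream keys are CRC-based,
independent of `PYTHONHASHSEED`). What the generator does **not** emulate:
chromatographic artifacts and carryover, detector saturation, ¹³C natural
abundance and multi-element correction, plate position effects, or
between-run response drift. Passing end-to-end tests therefore demonstrate
that the arithmetic chain inverts the assumed measurement model — not that
real spectra satisfy that model.

## Problem sizes and determinism

End-to-end tests run at the default conditions (4 ranks × 3 replicates ×
3 amino acids; qPCR plates of 6 genes × 4 conditions × 3 samples in
duplicate), with property suites of 100–1000 random cases; the full suite
and the demo pipeline each complete in well under a minute. All randomness
flows through explicit seeds; the pipeline writes a manifest (config
snapshot and hash, seed, per-stage status, SHA-256 of every output) and
reruns reproduce identical hashes.

## Known limitations

* The shift-convolution artifact model is an idealisation; the assays it
  mirrors only report the ~20 % M+1 magnitude, not the mechanism. Both
  implemented modes agree on M+0/M+1-only compounds.
* geNorm M is computed on relative quantities; it is invariant to per-sample
  scaling, but heavily unbalanced missingness between candidate genes is not
  handled (rows with missing candidates are dropped).
* The t-test and ANOVA assume equal variances by design, matching the
  analysis scheme they reproduce, and no multiple-testing correction beyond
  Tukey is applied.
* Quantification assumes a strictly linear detector response; response-factor
  drift across batches is out of scope.
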