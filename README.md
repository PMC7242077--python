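# leaftracer

Quantitative analysis of ¹⁵N isotope tracing, amino-acid quantification and
qPCR gene expression for leaf-disc assays, built around the workflow used to
study nitrogen allocation and proline metabolism across leaf ranks of winter
oilseed rape (*Brassica napus*).

## Who this is for

Plant physiologists running short-term ¹⁵N labelling experiments on leaf
discs (¹⁵NH₄Cl or ¹⁵N-amino-acid feeding) with LC-MS isotopologue readout,
plus efficiency-corrected RT-qPCR time courses — and anyone who wants the
arithmetic of those analyses as tested, reusable code rather than a
spreadsheet.

## What it computes

**¹⁵N labelling.** For an amino acid with *n* nitrogen atoms, the MS
acquisition gives intensities over isotopologues M+0..M+4. The fractional
labelling of isotopologue *x* is

    labelling(x) = [M+x] / Σ_y [M+y]

AccQTag derivatisation adds ~20 % artificial M+1 signal, modelled as a
one-mass-unit shift convolution with fraction *r* estimated from ¹⁵N-free
external standards and removed by exact recursive deconvolution. **Net
labelling** subtracts the T0 (natural-abundance) baseline of the same
experiment and sums to zero across isotopologues; its first moment
Σ_x x·net(x) is the mean number of ¹⁵N atoms gained per molecule.

**Net ¹⁵N allocation.** Amino-acid contents (µmol g⁻¹ DW) come from peak
areas normalised to a dl-3-aminobutyric-acid internal standard and inverted
through external calibration curves. Allocation — the flux proxy — is

    allocation [nmol ¹⁵N g⁻¹ DW] = content × mean labelled atoms × 1000

**qPCR expression.** Relative expression with measured primer efficiencies
(E = 10^(−1/slope) from dilution series), normalised to the geometric mean of
two reference genes: RE = E_t^(−Cq_t) / geomean_j(E_j^(−Cq_j)). Reference
candidates are ranked by geNorm stability (M value, with iterative
exclusion). Fold changes between consecutive time points per arm give
log₂(FC_treatment/FC_control) summaries.

**Statistics.** One-way ANOVA with Tukey HSD and compact letter display
across leaf ranks; equal-variance two-sided t-tests for paired conditions;
log-transform of expression before testing.

**Osmotic design.** PEG 6000 osmotic potential from the Michel & Kaufman
(1973) polynomial, Ψ(C, T), and its inverse for dose design. The assay dose
of 400 g kg⁻¹ at 20 °C gives −1.88 MPa.

A synthetic-data generator (`leaftracer.simulate`) produces isotopologue
tables, qPCR plates and quantification tables with the statistical structure
above (binomial isotopologue distributions, the M+1 artifact, lognormal
intensity noise, Gaussian Cq noise, stable references plus an unstable decoy
gene), with ground-truth sidecars, so the whole chain is testable end to end.

## Worked example

```sh
$ leaftracer osmotic --peg 400 --temp 20
Ψ(400 g/kg, 20 °C) = -1.88 MPa

$ leaftracer run --seed 1 --out results/demo
```

then, in Python:

```python
import pandas as pd
alloc = pd.read_csv("results/demo/allocation.csv")
print(alloc.query("amino_acid == 'proline'")
          .groupby("leaf_rank")["net_allocation_nmol_per_g"].mean())
```

prints

```
leaf_rank
L11     75.754112
L15    179.614490
L3      -0.016416
L7       7.584302
```

— the sink-to-source gradient of net proline biosynthesis: young sink leaves
(L15) allocate ~180 nmol ¹⁵N g⁻¹ DW to proline over the 4 h labelling,
dropping to ~76 in L11 and to essentially zero in the old source leaves
(L7, L3), while `results/demo/stats_letters.csv` carries the Tukey letters
(a/b/c/c) and `results/demo/qpcr_genorm.csv` shows the two stable reference
genes outranking the unstable decoy. The run's `labelling_summary.txt`
reports the artifact fractions recovered from the ¹⁵N-free standards
(r ≈ 0.20 for each amino acid).

The same analyses are available as library objects: build a
`LabellingExperiment(data, standards=...)` or
`QPCRExperiment(cq, primers, metadata=...)` from data frames and call
`.fit()` for a results object with tidy tables and a `summary()`.

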