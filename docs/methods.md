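# Methods

## The assay model

Targeted quantification assumes centroided full-scan MS1 data in which each
library lipid, if present, produces one dominant peak near its adduct m/z
and expected retention time. A peak matches a species when its signed
relative mass error, (observed − reference)/reference × 10⁶, is within the
ppm tolerance **and** its retention time is within the RT window of the
expected value. Both boundaries are inclusive (≤), so a peak sitting
exactly at the tolerance is a match; this avoids float-equality surprises
at the edge. When several peaks qualify, the **maximum-intensity** candidate
is used (a `sum` aggregation is available): maxima are robust against noise
shoulders and make results independent of peak-list ordering. A species
with no qualifying peak scores 0 — absence is data, not an error.

Defaults: ppm tolerance 5.0 (the calibration-level mass accuracy of
orbitrap-class instruments), RT window ±0.2 min (a typical UPLC peak
half-width). Both are exposed on every entry point.

TIC normalisation divides each sample row by its own sum **over the matched
library species** (the raw non-library ion current is not available once
extraction is targeted), making rows compositional: each row sums to 1, and
any per-sample scale factor (injection volume, source drift) cancels
exactly. The L/S ratio is a ratio of sums within one row, so it is
invariant to this normalisation as well.

Species that are zero in every sample are dropped (with a warning) before
PCA or PLS-DA — zero-variance columns cannot be autoscaled.

## Diagnostics

Premature is the positive class. For a cutoff c, prediction is
`premature` iff value < c; a value exactly at the cutoff classifies as
mature, mirroring the strict "< cutoff" convention of clinical
method-comparison tables. Sensitivity = TP/(TP+FN) and specificity =
TN/(TN+FP) are reported rounded half-up to whole percent (10/11 → 91%).
Default cutoffs: L/S 10.0 (the summed-intensity MS variant of the assay),
LBC 50×10⁹/L.

The bundled 33-sample comparison cohort contains seven mid-trimester
(18 GW) amniocentesis samples without a recorded birth outcome; they are
treated as premature outcomes during evaluation, since an 18-week fetal
lung cannot be mature. This yields the 11-premature / 22-mature split the
evaluation arithmetic requires.

## PLS-DA and VIP

The discriminant model is a univariate-response NIPALS PLS: X is
mean-centered and unit-variance scaled (the chemometrics default), y is the
0/1 class indicator, centered. Per component a: w = Xᵀy/‖Xᵀy‖,
t = Xw, loading p = Xᵀt/tᵀt, y-loading c = yᵀt/tᵀt, then X and y are
deflated. The y sum of squares explained by component a is SSYₐ = c²·tᵀt.
Successive score vectors are orthogonal by construction. If the residual y
becomes orthogonal to the residual X, later components are null rather than
an error.

VIP for variable j over A components:

VIPⱼ = sqrt( p · Σₐ SSYₐ·wₐⱼ² / Σₐ SSYₐ ),  wₐ unit-norm,

which forces Σⱼ VIPⱼ² = p; VIP > 1 marks above-average influence. Default
n_components = 2 (the score-plot convention); VIP uses all fitted
components. The biomarker rule applies **strict** inequalities — p < 0.05,
VIP > 1.1, FC > 2 — on raw (uncorrected) t-test p-values; the absence of
multiple-testing correction is deliberate and is a known caveat of this
style of screen. Fold changes are ratios of TIC-normalised group
arithmetic means, unlogged, with no pseudo-count: a zero premature-group
mean is surfaced to the user rather than patched.

The t-test is Welch's unequal-variance two-sided test — the robust default
when group sizes differ (e.g. 8 premature vs 20 mature).

## Pathway scoring

Over-representation uses the one-sided (upper-tail) hypergeometric test of
the hit/pathway overlap against a user-chosen background; Holm step-down
adjustment is applied across exactly the pathways tested in a call.
−log(p) uses the natural log by default (base 10 available) since the
convention varies between tools.

Pathway **impact** is Σ centrality(matched) / Σ centrality(all members),
with relative betweenness centrality (normalisation (n−1)(n−2)/2,
undirected; unreachable pairs contribute 0). Graphs without intermediary
nodes (complete graphs, ≤2 nodes) have zero total centrality and are
assigned impact 0 with a log note — peripheral involvement, not absence of
association. Impact is monotone under hit-set inclusion.

The bundled pathway graphs are synthetic toys (star, chain, complete K₄,
and an 8-node tree whose hand-derived centrality table ships as
`TOY8_CENTRALITY`); real KEGG-derived graphs are user-supplied through the
JSON pathway format and are never downloaded.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses rely on, not
raw spectra:

* **Panel**: class tallies fixed (88/27/23/13, 64 lecithins); neutral
  masses uniform in [400, 900] Da (unique to 4 decimals), RTs uniform in
  [1, 13] min; PE species carry [M−H]−, the rest [M+H]+.
* **Baselines**: per-species log-uniform across [10⁵, 10⁷], rescaled so the
  immature L/S ratio is 1.7 — the mean of the seven 18-GW rows of the
  bundled cohort (≈1.73).
* **Maturation**: in samples with mature lungs the lecithin baselines are
  multiplied by 1 + 19/(1 + e^(−0.8·(GW−36))) — a logistic surge with
  midpoint 36 GW, steepness 0.8/week and a 20× ceiling, encoding lecithin
  synthesis that begins late in the second trimester and rises rapidly
  around week 36. Premature lungs have not initiated the surge, so their
  lecithins stay at baseline. SM baselines are constant in GW by
  construction.
* **Noise**: per-species log-normal with σ = sqrt(ln(1+CV²)); biological
  CV 25% by default (technical QC CVs are an order of magnitude smaller),
  plus a per-sample global scale factor (CV 20%) that TIC normalisation
  removes. Peaks carry a uniform ±3 ppm mass error and 0.03 min RT jitter,
  both well inside the matching windows; 25 decoy peaks per sample at
  random m/z exercise matching specificity.
* **LBC**: normal draws truncated at 0 — control 18 GW N(2, 0.7),
  premature N(40, 8), mature N(57, 5) — placing ~10% of premature samples
  above the 50×10⁹/L cutoff and ~8% of mature below it, so the count
  misclassifies a minority of samples as it does clinically.
* **Group design**: default sizes follow the clinical study design —
  6 controls at 18 GW, 8 premature (<37 GW), 10 preterm-mature (<37 GW),
  10 term-mature (>38 GW).
* **QC replicates**: log-normal technical noise at class CV targets 3.8%
  (PC), 3.4% (SM), 3.6% for the rest, around a fixed pooled profile.

Every generator takes an explicit seed and is bit-reproducible; there is no
global random state.

What the simulations do **not** contain — chromatographic peak shapes,
isotope patterns, adduct interference, in-source fragmentation, RT drift
across batches, blood/meconium contamination, and any correlation
structure between lipids beyond the shared maturation factor. Passing
recovery tests therefore demonstrate that the code implements the intended
statistics faithfully under the assumed generative model, not that the
assay achieves these operating characteristics on real amniotic fluid.

## Problem sizes and numerics

The test and acceptance workloads use the study's own scale: the 33-sample
bundled cohort, 6 QC replicates, and simulated cohorts of 10 samples per
group with the 151-species panel — sizes at which every computation runs
in seconds. Tie-breaks and degenerate inputs are fixed explicitly: max-
intensity peak selection; equal-constant-group t-tests return p = 1;
all-zero sample rows fail normalisation with the sample named; zero
sphingomyelin fails the L/S ratio with the sample named; biomarker sorting
is fold-change descending with name-ascending tie-break, so output is
independent of input order.

## Design choices that were genuinely open

* **Which 64 of the 88 PCs are lecithins**: taken to be exactly the diacyl
  PCs — "lecithin" denotes diacyl phosphatidylcholine, and ether (O-, P-)
  and lyso PCs are chemically distinct; the synthetic panel is built with
  exactly 64 diacyl PCs. The true identities in any given lab's panel are
  configurable through the library CSV.
* **TIC denominator**: matched-species sum (see above) rather than the raw
  ion current, which a targeted extraction no longer has.
* **Enrichment background**: left to the caller (panel vs compound
  universe changes p-values materially); the pipeline uses the tested
  panel plus all pathway members.
* **Internal-standard correction**: real assays use spiked standards to
  correct matrix effects; no correction formula is modelled, and the
  simulator's multiplicative per-sample factor stands in for the drift
  such standards would absorb.
* **Config format**: YAML sections (`paths`, `params`, `simulate`, `seed`)
  with unknown keys warning rather than failing, for forward
  compatibility.
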