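# Methods

## Mass scale

All arithmetic is negative-mode: the only ion considered is [M − H]⁻,
with m/z = M − m(proton). Element monoisotopic masses are the CIAAW/IUPAC
values hard-coded to ≥ 9 decimals (cross-checked against rdkit's periodic
table in the test suite). The proton mass is *defined* as
m(H) − m(e⁻) = 1.00727645216 Da so that deprotonation is exactly
self-consistent on this scale; this differs from the CODATA free proton
by the hydrogen electron binding energy (≈1.5 × 10⁻⁸ Da, i.e. 0.0001 ppm
at m/z 150 — irrelevant at the 5 ppm tolerances used throughout).
Formula strings accept both plain (`C7H6O4`) and underscore-delimited
(`C_7_H_6_O_4_`) dialects because the transcribed annotation tables use
the latter; canonical output is Hill order.

## Screening criteria

Two threshold regimes coexist deliberately. The EIC ingest stage uses
area ≥ 1000 and intensity ≥ 500 (with optional S/N ≥ 3 when per-feature
noise estimates exist); target *confirmation* is stricter: |ppm| ≤ 5,
|ΔRT| < 0.2 min (strict, per the stated criterion wording), area > 1000
(strict) and intensity ≥ 1000. Both are configuration keys. Target
assignment is one-to-one greedy by match quality (smallest |ppm|, then
smallest |ΔRT|): no feature confirms two compounds and no compound gets
two hits per sample, which is what makes "23 spiked standards → 23
confirmed" a meaningful recovery statement even with isobaric standards
(luteolin/kaempferol, catechin/epicatechin) in the list. Suspects have no
standards, hence no RT criterion; every suspect within tolerance is
reported and suspects sharing a formula are flagged isobaric rather than
arbitrated. Fragment evidence is never required for a tentative ID —
any positive fragment score upgrades the level to *fragment-supported*.

## Quantification

Calibration curves regress response ratio (analyte area / internal-
standard area) on concentration over 0.05–20 mg/L (8 levels) with
1/x-weighted least squares (statsmodels WLS); 1/x weighting balances
relative error across the two-decade range. Back-calculation divides by
the curve slope and multiplies by the extraction dilution factor of
10 mL/g (1 mL solvent per 0.1 g flour), so extract mg/L × 10 = flour
mg/kg. Whether reported concentrations are per kg flour or per kg
extract solids is ambiguous in the source material; mg/kg flour is
adopted. Negative back-calculations are clamped to zero and flagged
below-quantification. Semi-quantification of suspects uses the identical
arithmetic with the same-class reference curve (flavanols → catechin,
flavonol glycosides → rutin, phenolic acids → gallic acid, stilbenes →
quercetin, secoiridoids/lignans/coumarins/phenols → vanillin); the
per-compound response-factor mismatch biases absolute values, but class
*ratios* cancel it — which is why fold changes are the quantity checked.
Triterpenoids have no same-class standard and are reported unquantified.

## Formula finder

Enumeration is exhaustive over CHNOPS bounds (defaults C ≤ 60, H ≤ 100,
N ≤ 10, O ≤ 30, S ≤ 6, P ≤ 4): heteroatoms are iterated, carbon is
vectorised and hydrogen is solved from the mass residual, which keeps a
single feature under ~10 ms at default bounds; a plain five-deep nested
loop serves as the completeness oracle in the tests. Scoring is
100 × (0.4·(1 − |ppm|/tol) + 0.6·plausibility): plausibility starts at 1,
is zero outside RDBE [0, 40], and is multiplied by 0.7 for each violated
element-ratio window (H/C ∈ [0.2, 3.1]; O/C ≤ 1.2 for C ≥ 3 — the usual
small-molecule heuristics). The weights favour plausibility over mass
error so that a chemically clean formula near the 5 ppm edge still
clears the 50.0 high-confidence gate, and the soft 0.7 penalty keeps a
mass-exact but ratio-atypical composition above it; the 50.0 gate itself
is retained from vendor-score convention, but the scale is this
package's own and is not comparable to vendor scores printed alongside
the transcribed tables (which are therefore not reproduction targets).
Isotope patterns are not used (single-stage accurate mass only).

## Alignment

Cross-sample alignment is greedy area-ranked centroid clustering:
features sorted by descending area seed clusters; a feature joins the
nearest cluster (by ppm, ties by ΔRT) whose area-weighted centroid lies
within both 5 ppm and 0.2 min, else seeds a new one. Missing values are
zeros (non-detection), so total area is conserved exactly — a property
the tests assert. No RT warping is attempted (single-batch design).

## Chemometrics

Pretreatment is log10(x+1) followed by per-feature autoscaling;
zero-variance features are dropped (with a tolerance for floating-point
residue). PCA is plain SVD. PLS-DA is NIPALS PLS1 with X-deflation,
y ∈ {0,1}, centred internally; with a single response the weight step is
closed-form, making the fit deterministic. R²Y is 1 − RSS/TSS of the
fitted response; Q² is 1 − PRESS/TSS under stratified 5-fold CV with
fold models fit on training rows only. VIP uses the SSY-weighted squared
weights; Σ VIP² = p holds to 1e-9 by construction and is asserted.
Bootstrap VIP resamples within class (original class sizes, with
replacement) 100 times and averages. The permutation test refits under
100 shuffled label vectors and declares the model valid only when every
permuted R²Y *and* Q² falls strictly below the original. ROC/AUC (tie-
corrected rank statistic) and the accuracy-at-optimal-threshold are
computed on *cross-validated* predicted scores, not resubstitution
scores — resubstitution would make perfect AUC trivial on p ≫ n data.
Two components are used throughout, matching the two-dimensional score
plots such data are judged by. All resampling is driven by one seeded
generator, so a report is bit-reproducible given (matrix, config, seed).

## Synthetic studies

The generator emulates the study design: two classes × 10 samples, an
internal standard at 1 mg/kg, per-compound class concentration means/sds
(reported values verbatim where available — e.g. kaempferol GSFC
3.22 ± 0.31 vs GSFL 2.20 ± 0.08 mg/kg; protocatechuic acid 95.7 ± 0.98
mg/kg in olive-stone flour; procyanidin A1 4.5-fold and epicatechin
gallate 5-fold higher in the island grape flour; diosmin and taxifolin
unique to island olive flour), CV 10% where no sd was reported, and
noise features to bring the consensus totals to 1042 (grape-seed) and
1620 (olive-stone). Concentrations are normals truncated at zero; the
response model is area = response_factor × extract mg/L × g_s × ε with a
shared per-sample instrument factor g_s that the internal-standard ratio
cancels and 5 % CV lognormal noise ε. Response factors are fixed
per-compound draws from Lognormal(ln 10⁵, 0.3) area·L/mg, chosen so the
least-concentrated reported standard (0.22 mg/L in extract) still clears
the 1000-count confirmation gates with margin. Feature positions respect
a minimum spacing (no two features within 12 ppm *and* 0.4 min), and
m/z / RT jitters are truncated normals (sd 1.5 ppm clipped at ±2 ppm;
sd 0.02 min clipped at ±0.08 min), which together guarantee that greedy
alignment recovers exactly one consensus feature per planted feature —
feature-count recovery is exact, not statistical. 56 (grape) and 99
(olive) noise features receive multiplicative class shifts (fold 2–4,
i.e. ≥ 3 within-class sd on the log scale): the planted discriminant
signal the VIP selection must find. MS/MS spectra are emitted for
compounds with library fragments, jittered within 10 ppm.

What the generator does *not* emulate: chromatographic drift and batch
effects, co-elution and detector saturation, isotope envelopes,
correlated biological covariance between compounds, and real fragment
intensities. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic and selection logic are correct under the assumed
noise model, not that the criteria are robust to instrument artefacts.

## Fixtures and their blemishes

The compound libraries are reconstructed from compound names; reference
RTs are synthetic (spread over the 20-min gradient, same-formula
compounds > 0.5 min apart) and expected fragments are synthetic
neutral-loss stand-ins, both labelled as such in the provenance column.
The transcribed annotation tables are kept verbatim, including rows
whose printed formula cannot match the printed mass (e.g. the
luteolin row at 285.0386 vs a theoretical 285.0405, ≈6.5 ppm; an
epicatechin gallate row whose printed formula is ~32 Da off the printed
mass); such rows are flagged `inconsistent` by a mechanical ≤ 5 ppm rule
and excluded from mass-consistency guarantees rather than corrected.
One enumerated target name (naringenin) has no matching standard in the
reagent list (naringin was supplied instead); the library keeps all 24
names with a flag and the default spike set uses the 23 with standards.
The coutaric acid class direction contradicts its reported values in the
source; both numbers are stored verbatim with a flag, and the generator
follows the stated direction.

## Problem sizes

Default test and acceptance runs use the full study conditions (20
samples, 1042/1620 features, 100 bootstraps, 100 permutations); a full
workflow run takes a few seconds. The null-model robustness check uses a
reduced 10-sample, ~34-feature configuration over 10 generator seeds,
which is ample to show that equal-mean generation does not produce
spuriously valid discrimination.
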