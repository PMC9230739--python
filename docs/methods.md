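# Methods

## The calibration model

The quantity of interest is the analyte content *y* (mg per dosage unit) of
a low-dose chlorpheniramine maleate (CPM) formulation, predicted from its
ATR mid-IR absorbance spectrum **x** on a fixed wavenumber grid. PLSR
relates the two through A latent factors extracted by NIPALS from the
column-mean-centered spectral matrix X and centered response y:

    w_a ∝ X'y / ‖X'y‖      (weight)
    t_a = X w_a            (score)
    p_a = X't_a / t_a't_a  (x-loading)
    q_a = y't_a / t_a't_a  (y-loading)
    X ← X − t_a p_a',  y ← y − q_a t_a   (deflation)

The regression vector in centered space is b = W(P′W)⁻¹q, exploiting that
P′W is unit upper triangular for NIPALS, and predictions are
ŷ = ȳ + (x − x̄)′b. With a univariate response the inner NIPALS iteration
converges in one pass; a guard loop (tolerance 1e-12 on the weight change,
max 500 iterations) covers degenerate inputs. No variance scaling is applied
to X or y: the spectral pretreatments do the scaling work, and unit-variance
scaling of absorbance channels is not standard in spectral PLSR.

**Assumptions.** Absorbance is (approximately) linear in component
concentration over the working range (Beer–Lambert in the thin effective ATR
sampling depth); nuisance variation (scatter, baseline) is either removed by
pretreatment or low-dimensional enough to be absorbed by extra factors; the
reference assay is unbiased up to a stable recovery factor.

## Pretreatments

* **SNV**: per-spectrum (x − mean)/sd with the sample (n−1) standard
  deviation. The (n−1) convention matches common chemometrics software; the
  alternative is a one-line change. SNV is invariant to affine transforms of
  its input, which several tests exploit as an oracle.
* **Area normalization**: division by Σ|xᵢ|, a discrete total-area proxy.
  A trapezoidal integral would differ only by the constant grid-spacing
  factor, which cancels after centering in PLSR; the absolute value keeps
  the denominator positive for derivative-shaped inputs.
* **Savitzky–Golay derivatives**: local least-squares polynomial of given
  order over an odd centered window, derivative scaled by the grid spacing
  (true d/d(cm⁻¹), grid-independent). Edges are handled by re-evaluating the
  first/last full-window polynomial at the off-center positions, so the
  matrix width never changes and interval bookkeeping never shifts. On a
  grid assembled from disjoint wavenumber intervals of one instrument axis,
  the filter runs independently per contiguous block; spacing that shrinks
  mid-grid is rejected as genuinely uneven.
* Recipes compose left to right: "area_norm+snv" means area normalization
  first, then SNV. The conventional "A + B" pretreatment notation does not
  state order; left-to-right is this package's reading, and recipes are
  explicit ordered lists so either order can be configured.

## Sample selection

Kennard–Stone picks the maximal-distance pair first, then greedily adds the
sample maximizing its minimum Euclidean distance to the selected set. Ties
break toward the lowest row index (lexicographically smallest pair for the
seed pair), making selection fully deterministic without a seed. Distances
are computed on raw absorbance spectra (optionally restricted to a model's
intervals), not on pretreated data — pretreatment choice should not change
which physical samples are in the calibration set. The split is applied
independently within each concentration stratum: the study design calls for
exactly 24 calibration + 6 validation units per strength, which a global run
cannot guarantee. A plain global `kennard_stone` is also exposed.

Granule campaigns use seeded uniform stratified sampling without
replacement (7 calibration per strength of 10).

## Cross-validation and complexity selection

`cross_validate` refits the model without each held-out sample/segment and
reports RMSECV and R²_cv = 1 − PRESS/SS_tot per factor count 1..A_max. The
default scheme is leave-one-out for n ≤ 100 and 10 seeded random segments
otherwise (the segment count follows common practice; the exact scheme used
by commercial packages is generally undocumented). The default complexity
rule is argmin RMSECV with ties toward fewer factors; a parsimony rule
(smallest A within (1+tol)·min RMSECV) is provided. Factor counts are
treated as data-dependent outcomes, not constants; `ModelConfig` can pin
them when an externally chosen complexity must be reproduced.

## Evaluation

RMSEP = √(Σ(ŷᵢ − y⁽ʳᵉᶠ⁾ᵢ)²/n) and bias = Σ(ŷᵢ − y⁽ʳᵉᶠ⁾ᵢ)/n, so
RMSEP² = bias² + population variance of the residuals (a test invariant).
Calibration R² is 1 − SS_res/SS_tot reported raw (it can be negative for
terrible models); validation R² is the squared Pearson correlation.
Method agreement uses a two-sided paired t-test on ŷ − y_ref (the
conventional choice for method-comparison at a stated confidence level;
a seeded sign-flip permutation variant is available). Heteroscedasticity —
residual spread growing with content — is quantified as the Spearman
correlation between |residual| and the reference value with a seeded
permutation p-value; visual residual plots motivate the diagnostic, the
rank test makes it reproducible.

## Model grid and selection

`builtin_grid` enumerates the standard candidate set: 13 tablet
configurations over ranges {400–4000, 2700–4000, 500–1700, 2500–4000,
500–1700 + 2500–4000} cm⁻¹ with {original, D2, area-normalized,
area-normalized+SNV, D1, D1+SNV}, and 11 granule configurations over
{400–3700, 400–1700 + 2800–3700} cm⁻¹ with {original, SNV, area
normalization, SNV+D1} sweeping the derivative over polynomial order 2–4 and
windows 11/21. Where a derivative row does not state its parameters,
poly 2 / window 11 is used (the workflow's default elsewhere).

`select_best` ranks successful rows by a weighted rank-sum: descending ranks
of R²(model) and R²(Pearson) plus ascending ranks of RMSEP and |bias|,
lowest sum wins, ties toward fewer factors then lower id. The default
weights double |bias|: among models with comparable precision, systematic
error is the decisive accuracy criterion for a quantitative assay, and the
doubled-bias composite reproduces the preference for the low-bias
selected-interval model over its near-twin on published-style metric rows.
Equal weights are available and land on the near-twin — the ranking is
parameterized precisely because narrative model choices weigh accuracy
differently.

## Synthetic data

The generator emulates the measurement campaign, not the optics:

* **Composition.** Seven builtin formulations (4, 8, 10, 15, 20, 25, 30 mg
  CPM per constant 132 mg unit) with lactose monohydrate traded against the
  analyte and fixed tapioca starch (40 mg), croscarmellose sodium (3.7 mg),
  corn starch (3.6 mg), magnesium stearate (0.7 mg).
* **Signal.** Each component contributes a Lorentzian band set (amplitude
  per unit mass fraction); a sample's clean spectrum is the mass-fraction
  mixture. CPM bands sit at 1700, 2900, 1640, 1600, 1100 and 880 cm⁻¹; the
  carbohydrate excipients carry broad O–H (~3300), C–H (~2920) and strong
  C–O–C (1000–1150 cm⁻¹) bands that overlap the analyte's C–O region by
  design — the low-dose interference the calibration must overcome.
  Lorentzian is the default line shape for condensed-phase mid-IR bands;
  Gaussian is available per band.
* **Artefacts.** Multiplicative scatter (1 + N(0, 0.05)), baseline offset
  N(0, 0.01 a.u.) and slope N(0, 2e-5 a.u./cm⁻¹), additive channel noise
  N(0, 0.002 a.u.) — magnitudes typical of a DTGS ATR acquisition on the
  default 400–4000 cm⁻¹ / 2 cm⁻¹ grid (1801 points).
* **Tablet vs granule.** The only modeled difference is `surface_sd`
  (default 0.08 for tablets, 0 for granules): ATR reads the unit surface,
  and an un-ground compressed tablet presents a surface CPM fraction
  wandering multiplicatively around the bulk mass ratio, balanced against
  the filler. The spectral error this injects is proportional to strength,
  which is what produces heteroscedastic validation residuals in tablet mode
  and near-nominal diagnostics in granule mode. The 0.08 scale was chosen
  from the variance budget — with strength variance ≈ 85 mg² and mean
  squared strength ≈ 333 mg², an 8% relative surface error yields RMSEP
  ≈ 1.5 mg and validation R² ≈ 0.96, the regime a well-behaved campaign of
  this design reports.
* **Reference values.** truth × recovery × (1 + N(0, rsd)) with defaults
  recovery = 1.015 and rsd = 0.0126, the midpoint recovery and repeatability
  of a validated HPLC assay for this analyte. Whole-unit truth equals the
  nominal strength: surface jitter affects what the spectrometer sees, not
  what the dissolved unit contains.

**What passing tests do not show.** The generator has no ATR
penetration-depth dispersion, no instrument line-shape convolution, no
atmospheric CO₂/H₂O interference, no water-content or particle-size
variation, and unit content is exactly nominal. Recovery of the qualitative
regime (R² ≈ 0.95–0.98, RMSEP ≈ 1–1.7 mg, SNV beating raw spectra under
scatter, tablet-mode heteroscedasticity) demonstrates the pipeline's
correctness and the stated mechanisms, not instrument-level accuracy on real
tablets.

## Numerical and design notes

* Interval bounds are inclusive at both ends; the canonical grid order is
  ascending wavenumber (FTIR plots descending; readers normalize). No
  implicit resampling: sets on different grids do not combine.
* Spectral ranges are never hard-coded: tablets conventionally use
  400–4000 cm⁻¹ and granules 400–3700 cm⁻¹, both expressed as ordinary
  interval selections.
* The SNV-vs-original contrast is assessed at matched model complexity
  (two factors): with an unconstrained CV-chosen factor count PLSR can spend
  an extra factor modelling the scatter dimension itself, which masks the
  pretreatment's benefit; the matched-complexity comparison isolates it.
* JCAMP-DX support covers uncompressed AFFN `##XYPOINTS`/`##XYDATA`
  (X++(Y..Y)) with XFACTOR/YFACTOR and transmittance→absorbance conversion
  (−log₁₀T, percent detected by values > 1.5); SQZ/DIF/DUP compression is
  rejected explicitly.
* HPLC back-calculation flags, rather than rejects, concentrations outside
  the 10–30 µg/mL calibrated range: the stated single dilution scheme puts
  the highest strengths above that range, so hard rejection would be
  unusable; flagging surfaces the issue to the analyst.
* Model JSON serialization round-trips float64 exactly, so a reloaded model
  re-predicts bit-identically (a test asserts this).
* Problem sizes in the test suite mirror the study design (210 tablet /
  70 granule spectra, 1801-point grid); repeated-seed checks use 20–25
  campaigns, which the variance of the asserted orderings comfortably
  tolerates.

## Known limitations

* Single-response PLSR only; no SIMPLS/kernel variants, no coefficient
  uncertainty.
* No MSC, detrending, OSC or wavelet pretreatments; no automated interval
  optimization (iPLS etc.) — candidate ranges are curated.
* The paired t-test assumes approximately normal differences; use the
  permutation variant for heavy-tailed residuals.
* Granule reference values are kept in mg/unit. Published granule-model
  error tables in this application area are sometimes an order of magnitude
  larger than tablet ones, suggesting a different reference unit (e.g.
  % label claim); that unit ambiguity is documented here, not emulated.
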