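# Methods

This note documents the statistical procedures implemented in `milknir`, the
assumptions behind the synthetic raw-milk generator, and the numerical and
design choices made where the standard workflow leaves them open.

## 1. The calibration problem

Raw milk is an aqueous emulsion; its NIR spectrum is dominated by water O–H
bands with weaker C–H/N–H overtone and combination bands from fat, protein
and lactose, all riding on strong, sample-dependent light scattering from fat
globules and casein micelles. A calibration maps a measured spectrum to a
component concentration (% w/w, i.e. grams per 100 g of milk). The pipeline
treats the spectrum as transmittance/reflectance referenced against white and
dark standards, `(S − D)/(W − D)`, optionally averaged over replicate scans,
and restricted to one instrument's physical wavelength window (closed
interval in nm; wavelengths are always physical nm at the interface, never
indices).

## 2. Preprocessing chains

A chain is the ordered composition

1. `Raw` or `Log` — absorbance via log₁₀(1/value);
2. `No` / `Base` / `Detr` / `SNV` / `MSC`;
3. `No` or Savitzky–Golay derivative `SG{x}D{yy}` (order x ∈ {1,2},
   2nd-order local polynomial, odd window yy);
4. `No` or one-component OSC;
5. mean centering (always).

The grid is the full Cartesian product, 2·5·21·2 = 420 chains; labels follow
the `Log|Detr|SG1D13|OSC|MNCN` grammar and round-trip through parsing.

Choices the chain definitions leave open, and how they are fixed here:

* **SG windows** — the ten odd lengths {3, 5, …, 21}. Derivatives are taken
  per index step (classic SG coefficients), treating the grid as uniform
  within one instrument; this matches standard chemometric practice and the
  `SGxDyy` naming convention. Edge points refit the quadratic on the
  truncated one-sided window.
* **`Base`** — offset correction (subtract each spectrum's minimum): the
  simplest baseline notion distinct from 2nd-order detrending.
* **`Detr`** — subtract each spectrum's least-squares quadratic in
  wavelength, computed via an orthonormalized Vandermonde basis on the
  centered/scaled abscissa for conditioning.
* **MSC** — reference is the calibration-mean spectrum; each spectrum is
  regressed `x ≈ a·ref + b` by ordinary least squares and corrected to
  `(x − b)/a`.
* **OSC** — Wold's one-component algorithm: a score capturing large spectral
  variance is orthogonalized against the (centered, normalized) response,
  the corresponding loading is deflated from X, and the stored weight vector
  deflates new spectra the same way. The plain power iteration has a
  degenerate dominant eigenvalue — every score orthogonal to the projection
  of y onto the spectral column space is a fixed point, and the component
  along that projection decays at rate (1 − ‖P_X y‖²), which can be
  arbitrarily slow. The implementation therefore starts the iteration at the
  closed-form limit (first principal score projected orthogonal to P_X y,
  using a rank-truncated pseudoinverse) and lets the iteration (tolerance
  1e-10, max 500 steps) certify the fixed point; fitted scores satisfy
  |corr(t, y)| < 1e-6 by construction.

All trainable state — MSC reference, OSC weight/loading and column means,
the centering mean — is estimated from calibration spectra only and applied
unchanged to new spectra. Every remaining step acts row-wise, so processing
one validation spectrum can never depend on the other validation spectra.

## 3. PLS1 core

Single-response NIPALS, which for one response is non-iterative: per
component, `w = Xᵀy` (normalized), `t = Xw`, `p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`,
then deflation of X and y. Coefficients for any component count are
`b = W(PᵀW)⁻¹q`; prediction is affine in the processed spectrum. X and y are
centered inside the fit even though mean centering already ran upstream —
harmless double-centering that makes the module safe standalone. The
cross-validation path requests coefficients for all counts 1..A at once;
counts beyond the effective rank repeat the last extractable model so that
low-rank (e.g. noise-free synthetic) data keeps a well-defined RMSECV curve,
while the strict `fit_plsr` entry point raises on rank exhaustion.

VIP scores use `VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)` with
`SSY_a = q_a² tᵀt`; mean squared VIP is identically 1.

## 4. Duplex split and cross-validation folds

Duplex operates on cow-level points — each cow is the mean of its autoscaled
sample compositions — so the blocking constraint (every cow entirely in one
set) is built in rather than patched on afterwards. The farthest remaining
pair (Euclidean distance, ties by lowest cow identifier) seeds calibration,
the next farthest pair seeds validation; thereafter repeating rounds of
(2 → calibration, 1 → validation) each assign the remaining point with the
largest minimum distance to the receiving set. Target sizes are
`n_val = ⌊n/3⌋`, remainder to calibration, reproducing 48/23 from 71 cows.

CV folds shuffle the calibration cows with a seeded generator and deal them
round-robin into k = 10 folds (48 cows → eight folds of 5 and two of 4).
Every fold refits the full preprocessing chain and PLSR from scratch on the
other nine folds.

## 5. Parsimony selection

All three selections use the same rule: rank candidates by RMSECV; starting
from the most parsimonious, accept the first whose absolute out-of-fold
residuals are not significantly worse than the best candidate's by a
one-sided paired t-test (α = 0.05), pairing by calibration sample. Zero
difference vectors count as "not worse"; a constant nonzero difference
decides by its sign. Applied to:

* latent count (parsimony = fewer latent variables; the OSC component is not
  counted here but is reported as `n_latent_total`);
* preprocessing chain (ties: lower RMSECV, then lexicographic label);
* wavelength-selection method (parsimony = fewer retained wavelengths; ties:
  fewer latent variables, lower RMSECV, method name).

No nested CV wraps the grid search, so the selected RMSECV is mildly
optimistic as an estimate of generalization error; the independent duplex
validation set is the unbiased check.

## 6. Wavelength selection

* **VIP** — retain VIP ≥ 1.0 (the greater-than-average-importance rule; the
  threshold is configuration).
* **Jack-knife** — Martens-style: coefficient variance estimated from the
  spread of the k segment models around the full-calibration coefficients,
  `s²_j = Σ_f (b_jf − b_j)² (k−1)/k`; retain wavelengths with
  `|b_j|/s_j` significant at α = 0.05 (t, k−1 df). The test is only
  approximately calibrated on null data. Degenerate zero variance counts as
  significant when the coefficient is nonzero.
* **RiPLS / FiPLS** — the grid is cut into `n_intervals` (default 20)
  contiguous intervals, the last absorbing the remainder; backward
  elimination / forward addition of whole intervals, each candidate
  cross-validated with its own latent-count selection, stopping when no move
  lowers RMSECV; ties go to the lowest interval index. Retained sets are
  unions of contiguous intervals and are reported as nm spans.
* An empty selection falls back to the single best wavelength with a warning.

## 7. Evaluation and spectrometer comparison

RMSEP and R²p are computed on the validation set (SST about the validation
mean). Williams bands grade R²: the printed bands leave 0.81–0.82 and
0.90–0.91 unassigned; the lower band is extended upward (documented,
arbitrary, isolated in one function). ICAR compliance is
`RMSEP ≤ {0.25, 0.20, 0.10}` % w/w for in-line / at-line / laboratory.

The cross-spectrometer comparison is a two-way ANOVA on per-sample squared
residuals with spectrometer as fixed factor and sample as a block. For this
balanced complete design the blocked fixed-effect analysis gives the same
F-test for the spectrometer factor as a mixed/repeated-measures model, which
avoids a mixed-model dependency. If the omnibus test is significant at
α = 0.05, Tukey HSD on the spectrometer means uses the ANOVA error mean
square and the studentized-range distribution; for k = 2 the adjusted p
equals the two-sided paired result. Compact letters use insert-and-absorb,
lettered from the lowest mean squared residual upward. Sums of squares that
are pure floating-point residue (< 1e-12 of SS_total) are treated as exact
zeros so that identical columns yield p = 1, not 0/0 noise.

## 8. Synthetic generator

The generator emulates a milking-parlor campaign: `n_cows = 71` cows with 3–5
samples each (≈ 280 samples). Compositions per component come from a
two-level model — a normal cow effect (SD = half the herd SD; the
within/between split is an assumption, stated and overridable) plus a
truncated-normal sample residual whose SD completes the target herd SD.
Default herd moments (% w/w): fat 4.715 ± 1.107 in [1.71, 7.7], protein
3.899 ± 0.415 in [2.99, 5.07], lactose 4.62 ± 0.154 in [4.09, 5.1].
Truncation enforces the bounds exactly and shrinks the realized SD slightly
(≈ 2 % for fat; more visible as a mean shift for asymmetric bounds like
protein's).

Spectra follow Beer–Lambert over a 1.5 mm cuvette path:
`A(λ) = L·(Σ_i c_i ε_i(λ) + c_w ε_w(λ))` with `c_w = 100 − Σ c_i`. The band
library is fictional-but-plausible configuration placed near known NIR
regions (fat C–H near 1210/1725/1765/2310/2350 nm, water O–H near 1450 and
1940 nm, protein and lactose combination bands at 2000–2300 nm) with
absorptivities scaled so the simulated transmittance stays measurable through
the short path. A per-sample affine scatter distortion
`A' = (1 + slope)·A + offset` (slope SD 0.15, offset SD 0.05 AU — strong
enough that scatter-correction steps have genuine work to do, as fat-globule
scattering does in practice) and i.i.d. Gaussian detector noise
(SD 0.002 AU) complete the model; output is transmittance `10^(−A')` (or
absorbance/reflectance on request). Everything is deterministic given the
config seed; compositions and spectra use independent seeded streams.

What the generator does **not** emulate: wavelength-dependent (Mie) scatter,
instrument line-shape convolution, detector nonlinearity, temperature drift,
fat creaming between sampling and measurement, or reference-analysis error.
Passing recovery tests therefore demonstrate correctness of the algorithms
under the stated statistical structure, not field performance on farm data;
synthetic prediction errors are markedly smaller than published on-farm
results.

## 9. Problem sizes and numerical tolerances

Tests and the acceptance script use deliberately compact campaigns — the
default 71-cow campaign at 5 nm steps over 2000–2450 nm (91 wavelengths), a
200-sample/101-wavelength noise-free recovery set, the 60-chain reduced grid
(`fast_chains`: every step option, one SG window) for selection runs, and
200-replicate Monte-Carlo checks for the ANOVA power property — chosen as the
smallest sizes at which every statistical property under test is comfortably
identified. The full 420-chain grid with 20 latent variables remains a
single-command option (`--grid full`). Key tolerances: noise-free recovery
RMSECV < 1e-6 of the component range; SG vs brute-force oracle 1e-9; PLSR vs
OLS 1e-8; VIP identity 1e-10; OSC score/response correlation 1e-6; exact
(1e-12-relative) RMSE bookkeeping identities.

## 10. Known limitations

* Duplex tie-breaking and the 2:1 assignment cycle are explicit conventions;
  other duplex variants yield slightly different (equally valid) splits.
* The jack-knife significance test is approximate; its null retention rate
  is near, not exactly, α.
* Greedy interval PLS is not globally optimal and can stop in a local
  minimum; interval count is a tunable with default 20.
* The grid-selection RMSECV is not nested-CV corrected (see §5).
* Loading real campaign data is supported through the documented CSV schema
  only; converters from external archive formats are deliberately out of the
  core readers.
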