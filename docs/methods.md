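# Methods

## Binding model and quenching analysis

The package assumes a reversible 1:1 (or n:1) association between a ligand L
and serum albumin P with association constant K_b. Quenching of the protein's
intrinsic tryptophan/tyrosine fluorescence reports complex formation:

* **Inner-filter correction.** Observed intensities are corrected for
  attenuation of excitation and emission light by the ligand,
  F_corr = F_obs·10^((A_ex+A_em)/2). Absorbance columns are optional; when
  absent the correction is the identity (instruments sometimes pre-correct,
  and dilute ligands often absorb negligibly). The correction is monotone in
  A_ex+A_em and exactly invertible.
* **Stern–Volmer.** F₀/F is regressed on [Q] by ordinary least squares over
  the nonzero-quencher points with a *free* intercept; a deviation of the
  intercept from 1 by more than 0.05 is reported as a diagnostic rather than
  forced away, since forcing the intercept hides curvature and
  inner-filter residuals. K_SV is the slope; k_q = K_SV/τ₀.
* **Quencher concentration.** [Q] is the *total added* ligand concentration
  in mol·dm⁻³. No free-ligand correction and no dilution correction are
  applied; this matches the printed regression forms the analysis is based
  on, and titration volumes are generally not reported.
* **Lifetime τ₀.** Defaults to 1.0×10⁻⁸ s, the conventional unquenched
  biopolymer fluorescence lifetime implied by the 2×10¹⁰ dm³·mol⁻¹·s⁻¹
  diffusion-limit criterion; exposed as a parameter (`--tau0`).
* **Mechanism call.** `static` requires K_SV strictly decreasing across the
  supplied temperatures *and* every k_q above 2×10¹⁰ dm³·mol⁻¹·s⁻¹;
  `dynamic` requires the opposite on both counts; everything else is
  `ambiguous`. With only three temperatures, strict monotonicity is used and
  no significance testing is attempted.
* **Double-log plot.** log₁₀((F₀−F)/F) on log₁₀[Q]: slope = n (binding
  sites), intercept = log₁₀K_b. Base 10 throughout. Points with F ≥ F₀
  (apparent negative quenching, typically noise at low [Q]) are excluded and
  counted in a warning; at least 3 usable points are required.
* **Analysis wavelength.** In the spectra dialect, F is always read at the
  emission maximum of the zero-quencher reference spectrum, held fixed for
  the whole titration, so a ligand-induced red shift cannot masquerade as
  quenching.
* **Site markers.** Apparent K_b is refitted in the presence of
  phenylbutazone (site I/IIA marker) and ibuprofen (site II/IIIA marker);
  whichever suppresses K_b more (both ratios < 1) identifies the occupied
  Sudlow site; ties or marker-enhanced binding give `indeterminate`.

## van't Hoff thermodynamics

ln K_b is regressed on 1/T: ΔH° = −slope·R, ΔS° = intercept·R with
R = 8.314 J·mol⁻¹·K⁻¹. The van't Hoff relation is sometimes typeset with
"log"; natural logarithms are used here so the linear form is algebraically
consistent with ΔG° = −RT·ln K_b without 2.303 factors. Energies are
computed in J·mol⁻¹ and reported in kJ·mol⁻¹ in tables. The force
classification is the standard sign table — (−,−) van der Waals/hydrogen
bonds, (+,+) hydrophobic, (−,+) electrostatic — with a 1e-9 tolerance so an
exactly zero fitted value maps to `indeterminate` instead of an arbitrary
sign. `spontaneous` means every fitted-temperature ΔG° < 0. ΔC_p is assumed
zero (linear van't Hoff); two temperatures produce an exact line and should
be treated as low-confidence.

## Circular dichroism

MRE = CD_obs(mdeg)/(10·C·n·l) with defaults n = 583 residues (BSA),
l = 1.0 cm, C = 1×10⁻⁶ mol·dm⁻³. Helix content uses the 208 nm estimator
with the standard anchors (pure α-helix magnitude 33 000, β/coil crossover
4000 deg·cm²·dmol⁻¹): helix% = (−MRE₂₀₈ − 4000)/29000·100. The ellipticity
at exactly 208 nm is obtained by linear interpolation on the wavelength
grid. Out-of-range percentages are reported unclamped with `in_range =
False` — clamping would hide bad concentration metadata. Helix *loss* is the
difference in percentage points between the free protein (ratio 0) and the
highest ligand:protein ratio. Full CD deconvolution (CONTIN/SELCON) and
222 nm estimators are out of scope.

## FT-IR amide-I deconvolution

1. Slice to the closed window [1600, 1700] cm⁻¹.
2. Subtract the straight line through the window endpoints. Noise can leave
   small negative excursions; values down to −5% of the peak are floored at
   zero, anything deeper raises a validation error (failed baseline).
3. Normalize to unit trapezoidal integral, making all downstream results
   invariant to intensity scaling.
4. Seed components at minima of a Savitzky–Golay second derivative
   (quadratic, 11-point default window) whose negative prominence exceeds
   1e-4 normalized units — the classical role of Fourier self-deconvolution
   (resolving overlapped bands) filled by a derivative method with no free
   apodization parameters.
5. Fit a sum of Gaussians (lmfit, Levenberg–Marquardt): centers constrained
   to seed ± 4 cm⁻¹, FWHM ∈ [5, 25] cm⁻¹, amplitudes ≥ 0; deterministic
   initialization (height at the seed, FWHM 12 cm⁻¹). Gaussian area uses the
   closed form height·FWHM·√(π/(4·ln2)).
6. Assign by center: β-sheet [1600, 1640), random coil [1640, 1650),
   α-helix [1650, 1660), β-turn [1680, 1691), β-antiparallel [1691, 1700];
   bins half-open except the top. The 1660–1680 cm⁻¹ region (turn/3₁₀-helix
   overlap) has no canonical single owner and is counted with β-turn but
   flagged. Class percentages are shares of total fitted area and sum to
   100 by construction.

Amide II, D₂O corrections and ATR penetration-depth correction are out of
scope.

## Synthetic data: what it emulates and what it does not

Generators sample **exactly the models the regressions assume**, so in the
noiseless limit each analysis stage is the generator's right inverse and
parameter recovery is exact by construction:

* Titrations: F = F₀/(1 + K_b[Q]ⁿ) with K_b(T) from the van't Hoff law;
  optional inner-filter attenuation (the analysis correction is its exact
  inverse); Gaussian noise of sd `noise_sigma`·F₀ on the nonzero points.
  An optional `mass_action=True` mode solves the free-ligand 1:1
  equilibrium instead, which reintroduces the real-world bias of treating
  total ligand as free in the double-log plot — useful for robustness
  studies, not for recovery tests.
* CD: two negative Gaussian lobes at 208/222 nm scaled so CD(208 nm)
  encodes the programmed helix fraction exactly through the MRE anchors.
* FT-IR: a sum of Gaussians with class areas equal to the programmed
  fractions, on a gentle linear baseline, 0.5 cm⁻¹ grid over
  1580–1720 cm⁻¹.

Default scenario constants encode the reference study design: BSA 1×10⁻⁶
mol·dm⁻³, ligand:protein ratios 0.1–2.0 in 0.2 steps, temperatures
297/303/308 K, ΔH° = −40 kJ·mol⁻¹ and ΔS° = −39 J·mol⁻¹·K⁻¹ (giving
K_b(297 K) ≈ 9.95×10⁴ dm³·mol⁻¹ ≈ 10⁵, n = 1), F₀ = 1000 a.u., emission
peak 348 nm / FWHM 50 nm (typical tryptophan emission), marker attenuation
factors 0.9 (phenylbutazone) and 0.5 (ibuprofen) so the reference compound
binds Sudlow site II. The structural scenario mirrors free BSA — 53.8%
α-helix (1658 cm⁻¹), 29.2% β-sheet (1632 cm⁻¹), 17.0% β-turn (1685 cm⁻¹) —
and a CD helix fraction eroding from 0.600 to 0.557 (4.3-point loss) across
ratios 0/0.5/1/5/10. Structural noise defaults to 0.2% of peak signal,
conservative relative to the 0.5% level at which class recovery is still
within ±2 percentage points; titration noise defaults to 0.

Because the generators sample the analysis models, passing recovery tests
demonstrates **internal correctness** (the code fits the model it claims
to fit), not robustness to real-data pathologies: scattering, drifting
baselines beyond linear, photobleaching, instrument response, concentration
errors, or genuine deviations from 1:1 ground-state quenching. The
`mass_action` switch probes exactly one of those gaps.

All randomness flows through one seeded NumPy generator per simulation call
(sub-streams spawned per temperature/marker/ratio), so identical scenario +
seed gives bit-identical output.

## Numerical choices

* OLS via `scipy.stats.linregress`; a constant response fits exactly with
  slope 0 and r² defined as 1 (0/0 convention on a perfect fit).
* Double precision throughout; van't Hoff recovery on noiseless inputs is
  accurate to ~1e-10 relative despite the narrow 1/T range.
* Report CSVs are written with pandas defaults; titration/spectrum files
  use `%.17g` so a write→read round trip is lossless.
* Problem sizes are the study design's own: 10-point titrations, 91-point
  CD grids, 281-point amide-I grids — the whole suite runs in seconds.

## Druglikeness

Classic thresholds: Ro5 violations over {MW > 500, logP > 5, HBD > 5,
HBA > 10}, pass at ≤ 1 violation; Veber rotatable bonds ≤ 10 and
TPSA ≤ 140 Å²; standalone TPSA screen < 140 Å². Descriptor *computation*
from structures is out of scope; the rule engine consumes a user-supplied
table.

## Known limitations

* No modified Stern–Volmer (Lehrer) analysis, no global multi-temperature
  fitting, no lifetime measurements.
* [Q] as total ligand biases K_b when binding depletes the free pool
  appreciably (protein ≈ ligand concentrations), as the mass-action
  generator demonstrates.
* The CD estimator uses a single wavelength (208 nm); crowded spectra or
  aromatic contributions will bias it.
* FT-IR class percentages depend on the band-assignment windows; components
  near bin edges can switch class with small calibration offsets.
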