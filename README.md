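# albind

Characterization of small-molecule binding to serum albumin from three
spectroscopies, for medicinal chemists and biophysicists running
drug-candidate / BSA (bovine serum albumin) titrations:

* **Fluorescence quenching** — inner-filter correction
  (F_corr = F_obs·10^((A_ex+A_em)/2)), Stern–Volmer analysis
  (F₀/F = 1 + K_SV[Q], k_q = K_SV/τ₀) with a static/dynamic mechanism call
  against the 2×10¹⁰ dm³·mol⁻¹·s⁻¹ scatter-collision limit, and the
  double-logarithm binding plot log₁₀((F₀−F)/F) = log₁₀K_b + n·log₁₀[Q]
  for the association constant K_b and binding-site number n.
* **Thermodynamics** — van't Hoff regression of ln K_b on 1/T for ΔH°, ΔS°;
  ΔG° = ΔH° − TΔS° = −RT·ln K_b; dominant-force classification from the
  (ΔH°, ΔS°) sign pattern; Sudlow-site assignment from phenylbutazone /
  ibuprofen competition.
* **Circular dichroism** — mean residue ellipticity
  MRE = CD_obs/(10·C·n·l) and α-helix% = (−MRE₂₀₈ − 4000)/29000·100 per
  ligand:protein ratio, with the helix loss across the titration.
* **FT-IR** — amide-I (1600–1700 cm⁻¹) deconvolution: baseline removal,
  area normalization, second-derivative component seeding, constrained
  Gaussian band fitting, and structure-class area percentages
  (β-sheet / random coil / α-helix / β-turn / β-antiparallel by center
  wavenumber).
* **Druglikeness** — Lipinski Ro5, Veber and TPSA screens over a supplied
  descriptor table.
* **Synthetic data** — generators for all three spectroscopies that sample
  exactly the models the analyses assume, with known ground truth, so every
  stage is verifiable by parameter recovery.

## Worked example

Simulate the reference titration design (BSA 1×10⁻⁶ mol·dm⁻³, ligand:protein
ratios 0.1–2.0 in 0.2 steps, 297/303/308 K) and run the full quenching →
thermodynamics chain:

```python
import albind as ab

scenario = ab.default_scenario()          # dH = -40 kJ/mol, dS = -39 J/mol/K
series = ab.simulate_titration(scenario, 297.0)
print(ab.fit_stern_volmer(series).summary())
print(ab.fit_double_log(series).summary())

kb = {T: ab.fit_double_log(ab.simulate_titration(scenario, T)).Kb
      for T in scenario.temperatures}
vh = ab.fit_vant_hoff(kb)
print(vh.summary())
print(ab.classify_interaction(vh).summary())
```

prints

```
Stern-Volmer fit
  temperature     297.0 K
  K_SV            9.954e+04 dm3 mol-1 (se 0)
  intercept       1.0000
  k_q = K_SV/tau0 9.954e+12 dm3 mol-1 s-1 (tau0 = 1e-08 s)
  r^2             1.000000  (n = 10)

Double-logarithm binding fit
  temperature  297.0 K   marker: none
  Kb           9.954e+04 dm3 mol-1 (log10 Kb = 4.9980)
  n (sites)    1.0000
  r^2          1.000000  (n = 10, excluded = 0)

van't Hoff fit (ln Kb vs 1/T)
  dH  -40.00 kJ mol-1 (se 0)
  dS  -39.00 J mol-1 K-1
  r^2 1.000000
  dG(297 K) -28.42 kJ mol-1
  dG(303 K) -28.18 kJ mol-1
  dG(308 K) -27.99 kJ mol-1

Interaction type: vdW_or_H_bond (spontaneous; dH = -40.00 kJ mol-1, dS = -39.00 J mol-1 K-1)
```

Reading: the recovered K_b ≈ 1×10⁵ dm³·mol⁻¹ with n ≈ 1 indicates a
one-to-one complex; k_q far above 2×10¹⁰ dm³·mol⁻¹·s⁻¹ together with K_SV
falling at higher temperature indicates static quenching (ground-state
complex); negative ΔH° and ΔS° with negative ΔG° indicate a spontaneous
association driven by van der Waals forces and/or hydrogen bonds.

The same chain is available from the shell:

```sh
albind simulate --out demo --seed 42
albind fluor --inputs demo/fluor --out demo/analysis
albind ftir  --input demo/ftir_amide1.csv --out demo/analysis
albind cd    --inputs demo/cd --out demo/analysis
```

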