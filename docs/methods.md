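# Methods

## Scope and model

The package treats a pulse-radiolysis experiment on N₂O-saturated
aqueous solutions of two thioether dipeptide models (0.2 mM substrate,
~11 Gy electron pulses, 1 cm optical path, 270–700 nm observation
window) as three connected computations:

1. **Dosimetry and yields.** G-values are the bridge between absorbed
   dose and concentration: c = G·10⁻⁶·D·ρ with D in Gy and ρ in
   kg L⁻¹ (fixed at 1.0 for dilute aqueous solutions, configurable).
   The total scavengeable radical yield follows the Schuler formula
   G(S•) = g0 + g1·√(a[S])/(1+√(a[S])) with g0 = 0.539 µmol J⁻¹,
   g1 = 0.307 µmol J⁻¹, a = 19.6 M⁻¹.  At the 10 mM thiocyanate
   dosimeter concentration the formula gives 0.6332 µmol J⁻¹ while the
   conventional rounded dosimetry constant is 0.635; the ~0.3%
   difference traces to rounded constants and is retained, not
   reconciled — the dosimeter conversion uses 0.635, the formula
   reports its own value.

2. **Spectral resolution.** Each OD(λ) slice is converted to Gε(λ) and
   regressed on the reference basis ε_j(λ) by non-negative least
   squares (`scipy.optimize.nnls`).  Non-negativity is imposed because
   the coefficients are physical yields; an unconstrained solve is
   available as a diagnostic and agrees with NNLS whenever the true
   solution is strictly interior.  Weighting is uniform across
   wavelengths; the library is always interpolated onto the data grid,
   never the reverse.  A condition number above 10⁸ triggers a
   collinearity warning but still returns the solution.

3. **Kinetics.** Reaction schemes are mass-action networks integrated
   with `scipy.integrate.solve_ivp` (LSODA, analytic Jacobian,
   rtol 10⁻⁸, atol 10⁻¹⁴ M); the substrate is a fixed-concentration
   species, making HO•/S•⁺ + substrate steps pseudo-first-order at
   0.2 mM.  Equilibria (SS•⁺, SN•) are explicit forward/reverse
   elementary pairs.

## Reference-spectrum parametrisation

The true transient reference curves are not redistributable, so each
species is a sum of Gaussian-in-wavelength bands,
ε(λ) = ε_max·exp(−4·ln2·(λ−λ_max)²/FWHM²), anchored exactly at the
literature peak values:

| species | λmax (nm) | εmax (M⁻¹cm⁻¹) | default FWHM (nm) |
|---------|-----------|----------------|-------------------|
| HOS•    | 340       | 3400           | 90 |
| αC(1)•  | 270 / 370 | 6200 / 1800    | 50 / 100 |
| αC(2)•  | 340       | 2000           | 40 |
| αS•     | 290       | 3000           | 60 |
| SS•⁺    | 480       | 6880           | 100 |
| SN•     | 390       | 4500           | 80 |
| SO•⁺    | 400       | 3000           | 90 |

Widths are per-species design parameters, not fitted quantities.  They
were chosen on two grounds: plausibility (broad adduct and
three-electron-bond visible bands, narrower UV carbon-radical bands)
and identifiability — HOS• and αC(2)• share a 340 nm peak, and with
equal widths their basis vectors would be exactly proportional, making
the regression rank-deficient; the 90 nm vs 40 nm width contrast keeps
the compound-1 six-species basis at a condition number of ~26.  All
widths are overridable per band, and tabulated curves (CSV) take
precedence over the parametric form when supplied.  αS(1)• and αS(2)•
share a single pooled `aS` entry because the optical experiment cannot
distinguish them.

## Kinetic defaults

Printed constants: HOS• decay k_d = 5.6×10⁵ s⁻¹; S•⁺→SO•⁺ lower limit
6×10⁷ s⁻¹; H• + substrate 1.7×10⁹ M⁻¹ s⁻¹.  The remaining constants
are package defaults inside the accepted typical ranges for these step
types ((5–7)×10⁵ s⁻¹ unimolecular, ~10¹⁰ M⁻¹ s⁻¹ HO• addition,
~10⁸ M⁻¹ s⁻¹ sulfur–sulfur association):

| parameter | compound 1 | compound 2 | meaning |
|-----------|-----------|-----------|---------|
| k_add     | 10¹⁰      | 10¹⁰      | HO• + substrate, total (M⁻¹s⁻¹) |
| f_adduct  | 0.75      | 0.70      | fraction of HO• flux to HOS• |
| f_ac1 / f_as / f_ac2 | 0.15 / 0.05 / 0.05 | — / 0.20 / 0.10 | direct-abstraction split |
| k_d       | 5.6×10⁵   | 5.6×10⁵   | HOS• → S•⁺ (s⁻¹) |
| k_hos_so  | —         | 10⁶       | carbonyl-assisted HOS• → SO•⁺ (s⁻¹) |
| k_ss_f / k_ss_r | 10⁸ / 10⁴ | 10⁸ / 10⁴ | S•⁺ + M ⇌ SS•⁺ (M⁻¹s⁻¹ / s⁻¹) |
| k_dep     | 2×10⁵     | 5×10⁷     | S•⁺ → αS• deprotonation (s⁻¹) |
| k_sn_f / k_sn_r | 8×10⁴ / 10⁴ | — | S•⁺ ⇌ SN• (s⁻¹) |
| k_sn_ac2 / k_sn_ac1 | 2×10⁴ / 10⁴ | — | SN• → αC channels (s⁻¹) |
| k_so_f    | —         | 6×10⁷     | S•⁺ → SO•⁺ (s⁻¹) |
| k_so_ac2  | —         | 3×10⁴     | SO•⁺ → αC(2)• (s⁻¹) |
| k_rr      | 10⁹       | 10⁹       | generic radical–radical sink (M⁻¹s⁻¹) |

The HO• partition (0.75 adduct / 0.25 abstraction for compound 1)
reflects the early-time dominance of HOS• (~73% of the radical pool at
1 µs); the much faster deprotonation and SO cyclisation of compound 2
produce the diagnostic contrasts the package asserts: an earlier and
lower HOS• maximum, negligible SS•⁺, and for compound 1 αS• as the
dominant radical from 10 µs onward.  The radical–radical sink is a
single generic channel over all radical pairs; with the observed ~6 µM
radical pool and k_rr = 10⁹ M⁻¹ s⁻¹ it erodes the pool on the
~100 µs scale, as observed.  SN(1)/SN(2) are pooled into one SN species
(matching the pooled reference spectrum) with separate product
channels to αC(1)•/αC(2)•.

## Product accounting

Monoisotopic masses use a hard-coded isotope table (H 1.00782503,
C 12 exactly, N 14.00307401, O 15.99491462, S 31.97207069) and the
proton mass 1.00727646 for MH⁺ (never the H-atom mass).  Every carbon
radical of one parent is the parent minus one hydrogen, so all
coupling dimers of a compound share one formula: the m/z dispersion
within a compound's dimer set is exactly zero.

Stereochemistry registry: aS1 = primary •CH₂–S radical (keeps the
parent S centre, creates none); aS2 = secondary radical α to sulfur
(keeps the S centre, creates one new centre); aC1 = backbone Cα radical
(the parent centre is destroyed and re-formed on coupling: 0 fixed,
1 new); aC2 = primary •CH₂ on the N-methyl amide (1 fixed, 0 new).
This is the unique assignment consistent with all reported
diastereoisomer counts and with the greater stability of secondary over
primary alkyl radicals.  Counting enumerates R/S assignments of new
centres, identifying half-swapped descriptors for homodimers
("identical halves" means the same radical name) and, when
`merge_enantiomers` is set (default true: achiral LC cannot separate
enantiomers), global mirror images of products with no fixed centre.
All reported counts contain fixed S centres and are invariant to the
flag.  Peak matching uses a 5 ppm default window and flags ambiguous
(isobaric) assignments rather than choosing one.

## Synthetic data

The generator emulates: Beer–Lambert superposition of the reference
spectra weighted by simulated G(t); dose/path scaling; additive
Gaussian OD noise of σ = 5×10⁻⁴ absorbance (detector-limited shot
model; chosen so the 290–490 nm features are clearly above noise at
11 Gy, where σ corresponds to ~45 Gε units).  One named
`numpy.random.Generator` per dataset, seed recorded in the sidecar
metadata; ground truth (profile and scheme) always serialised next to
the noisy data.  Not emulated: lamp drift, scattered light, baseline
structure, wavelength-dependent noise, chromatographic retention.
Passing round-trip tests therefore demonstrates correctness of the
forward/inverse algebra and noise robustness of the regression — not
robustness to the structured systematics of real detectors.

LC–MS peak lists place adduct/dimer peaks at exact MH⁺ with
multiplicative log-normal intensity noise (σ = 0.05); since all
adducts of one compound are isobaric, the generated list carries a
ground-truth `species` column standing in for the retention-time
separation that is not modelled.

## Numerical choices and degenerate inputs

* NNLS on a 216-point grid with ≤ 6 species; a minimum of 2 grid
  points per fitted species is enforced.
* Argmax ties in `species_tmax` resolve to the earliest time; an
  all-flat trace warns.
* Percentages are reported both as raw fractions and rounded integers
  (presentation form); an all-zero composition is an error rather than
  0/0.
* Formula subtraction below zero, negative ε, non-ascending grids,
  cross-parent radical coupling and unknown species identifiers all
  raise immediately with the violated invariant named.
* Default problem sizes (25–80 time points, 2 nm wavelength grid,
  20-seed Monte-Carlo batches) keep a full test run in a few seconds
  while leaving the Monte-Carlo standard errors well below the asserted
  tolerances.

## Known limitations

* Gaussian bands are a declared stand-in for the true reference
  curves; absolute yields resolved from *real* spectra with these
  shapes would inherit shape error.  Peak anchors are exact, so
  synthetic round trips are unaffected.
* Rate constants not fixed by the literature are plausible defaults,
  not fits; no acceptance-grade quantity depends on them, and fitting
  them to real traces is out of scope.
* Slice-by-slice resolution only; no global kinetic-spectral fitting,
  no baseline/scatter correction.
* The kinetic schemes omit secondary chemistry of the sink products
  and treat the radical–radical termination as a single generic rate.
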