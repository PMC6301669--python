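# Methods

## Model

A CT voxel's value under a polychromatic beam is modelled through the
detected spectral weight `S(E) = Φ(E) · exp(−μ_filter(E) t) · D(E)`:
tube fluence, beam filtration, and the single-photon detector signal.
For a substance present at molar density `n` with independent-atom molar
cross section `σ(E)` (m²/mol), the effective attenuation ratio is

    μ* = n ⟨σ⟩_S / (n⁰ ⟨σ_water⟩_S),     ⟨f⟩_S = ∫ S(E) f(E) dE,

normalized so water at its reference density reads μ* = 1 at every
voltage, filter and detector.  Two intensive quantities follow:

- molar HU potency  `p = 1000 ⟨σ⟩_S / (n⁰ ⟨σ_water⟩_S)`  (AHU·m³·mol⁻¹),
- mass HU potency   `η⁽ρ⁾ = p ρ⁰ / (1000 M)`  (dimensionless, water = 1),

with `ρ⁰ = 998 kg/m³`, `M` the molar mass, and
`n⁰ = ρ⁰/0.018015 ≈ 55 400 mol/m³`.  AHU = HU + 1000 places water at
1000 AHU and vacuum at 0, which makes potency exactly proportional to
concentration; the scale constant for water is 1000/998 ≈ 1.002
AHU·m³·kg⁻¹.  Both potencies are invariant to rescaling the fluence or
detector response (ratio structure), additive over stoichiometry, and
independent of bulk density.

### Assumptions

- **Independent-atom approximation**: a compound's cross section is the
  stoichiometric sum of its elements'.  Chemical-bond and fine-structure
  effects are outside the model; they surface as projection residuals.
- **No beam hardening within a sample**: the spectral weight is treated as
  sample-independent, appropriate for thin samples or
  hardening-corrected reconstructions.
- **Elements Z ≤ 20, energies ≥ 5 keV**: no K edges intrude above 5 keV
  (calcium's sits at 4 keV), so cross sections are smooth and near
  power-law; log–log linear interpolation is used when resampling
  tabulated data.  High-Z contrast agents are out of scope.

## Data

The packaged table (`data/powder_potency.csv`, SHA-256 checked at load)
holds measured mass potencies for 30 powders plus water at 80, 100, 120
and 140 kV.  Two printed formulas were curated during transcription:
"potassium carbonate" and "sodium carbonate" appear in the source table
with charge-unbalanced formulas (K₆CO₃, NaCO₃); the packaged dataset
stores the chemically correct K₂CO₃ and Na₂CO₃, which the compound names
identify unambiguously and which are consistent with the downstream
singular-value structure.  Air was scanned in the original experiment but
is not a table row; all observation counts below use the 31 × 4 = 124
packaged cells.

Atomic masses are the IUPAC 2021 conventional standard atomic weights
(natural isotopic abundance) for Z = 1..20, stored to five significant
figures in kg/mol.

## Pipeline

1. **Conversion.**  `p = η⁽ρ⁾ · (1000/ρ_water) · M` per compound and
   voltage gives the compounds × voltages molar-potency matrix H.
2. **Projection.**  `A = argmin ‖CA − H‖²_F`, solved per voltage by
   orthogonal-decomposition least squares (`numpy.linalg.lstsq`); the
   31 × 13 design matrix C counts atoms per formula unit.  C has full
   column rank; rank deficiency raises.  An explicit normal-equations
   routine serves as an independent oracle in the tests only.
3. **SVD.**  `A = U diag(s) Vᵀ` with a deterministic sign convention
   (largest-magnitude component of each left vector made positive).
4. **Rank selection.**  For k = 1..4 the rank-k surrogate of A is scored
   against H by `B(k) = N_p ln N_o − 2 ln L` with the Gaussian profile
   likelihood `2 ln L = −N_o (ln(2π RSS/N_o) + 1)`; the argmin selects the
   dimensionality.  (Conventions differ on the sign of the criterion; the
   minimized form is used so "the best model is the minimum".)
5. **Power law.**  `|u₁| ≈ a Z^b` is fitted by least squares in linear
   coordinates (default), which weights the large high-Z components; a
   log–log regression with equal weight per element is available via
   `fit="loglog"`.  The u₁-versus-Z curve is not an exact power law —
   its local slope steepens from ~1 at low Z to ~4 near calcium — so the
   two conventions give different exponents (2.49 vs 1.45 on the packaged
   data); the linear fit is the package's reported summary.

### BIC variants

Two choices are deliberately exposed because no single pair serves both
use cases:

- `rss_mode`: `"truncate"` (default) scores `‖C A_k − H‖²` with A_k the
  Frobenius-optimal truncation of A; `"refit"` re-estimates the
  per-voltage coefficients within the span of the first k left vectors,
  giving the best fit the retained basis allows and a properly nested RSS
  sequence.
- `n_params`: `"rank"` (default) counts one parameter per retained
  component; `"full"` counts `k(rows + cols − k)`, the free parameters of
  a rank-k matrix.

On the measured data the residual floor is independent-atom model error,
and all four combinations put the minimum at k = 2.  On noise-dominated
synthetic data the default pair is *not* consistent: the A-space
truncation of a noisy least-squares estimate is not the best rank-k fit
to H in the C-metric (hydrogen's potency is weakly determined yet its
design column carries counts up to 24), so discarded noise components
re-inflate the RSS and the criterion drifts to full rank at any noise
level.  The consistent pair `rss_mode="refit", n_params="full"` recovers
the true rank essentially always in the test suite's simulations and is
what the statistical property tests use.

## Filter calibration

The spectral model's one free parameter, the equivalent aluminum filter
thickness, is fitted by minimizing
`χ²(t) = Σ (ln p_obs − ln p_model(t))²` over the 52 element × voltage
cells (logs keep the small low-Z potencies from being underweighted).
Bounded scalar minimization on [0, 60] mm to 0.01 mm; the 95% CI collects
thicknesses with `Δχ² ≤ 3.84` after rescaling the residual variance by
`χ²_min/(N−1)`, and may be asymmetric.  Residuals are unweighted (no
per-point uncertainties are available).  A minimum on the search boundary
raises rather than being reported as a fit.  Under 5% log-normal noise
the CI covers the generating thickness in ~92–95% of seeded replicates —
the mild undercoverage expected of the profile-χ² approximation at this
sample size.

## Synthetic generators

The synthetic physics module emulates the *structure* of the real inputs,
not their tabulated values:

- **Cross sections**: `σ_Z(E) = a Z^4.5 E⁻³ + Z σ_KN(E) N_A`, a
  photoelectric power law plus Klein–Nishina scattering from Z quasi-free
  electrons.  The amplitude `a` is set once so the two terms balance for
  oxygen at 30 keV, a physically plausible division for diagnostic
  energies.  Positive and strictly decreasing on 1–200 keV.
- **Spectra**: Kramers continuum `Φ(E) ∝ E₀/E − 1` with a hard cutoff at
  the tube voltage; characteristic tungsten lines are omitted.  Exact
  theory numbers (published theory singular values, the ~23 mm filter
  fit) require tabulated XCOM/TASMICS inputs through `load_xcom` /
  `load_tasmics`; with the synthetic physics the same pipeline yields an
  interior filter fit (~28 mm), theory-versus-experiment RMS deviation
  ~12%, and theory singular values within ~6% of the experimental ones —
  structurally faithful, numerically approximate.
- **Compound tables**: `H = C A_true + ε`, `ε ~ N(0, sd²)` i.i.d. on the
  molar-potency scale (the scale the projection operates on; noise on raw
  HU would additionally couple to packing density), converted back to the
  mass potencies a scanner reports.  Noise large enough to drive small
  potencies (graphite ≈ 0.01 AHU·m³·mol⁻¹) negative violates the record
  invariants by design.
- **Bottle volumes**: axis-aligned cylinders (fill + wall shell) in air,
  HU = 1000(μ* − 1), optional Gaussian HU noise and an
  integral-conserving Gaussian edge blur standing in for finite
  reconstruction resolution.  The exact discretized μ* integrals are
  returned as oracles.  Default voxel pitch in the drivers is
  0.25 × 0.25 × 0.5 mm over a 64 × 64 × 32 grid — a bottle-sized crop at
  near-clinical resolution, kept small so the simulations run in seconds.

Passing tests on these generators demonstrates the pipeline's algebra,
statistics and segmentation logic; they do not validate the physics
tables themselves, beam-hardening behaviour, scatter, or scanner-specific
effects.

## Volume workflow

Segmentation is a plain HU threshold inside a user-supplied bounding box;
`μ* = 1 + HU/1000`; `η⁽ρ⁾ = ρ⁰ (∫μ*_filled − ∫μ*_empty)/M`.  (The
mass–integral relation is implemented in the form consistent with the
potency definitions: the mass-potency factor divides the mass, not the
integral.)  With blurred walls the threshold should sit low enough
(≈ −800 HU against an air background) to capture the blurred skirt; the
drivers report recovery within ~0.6% at 5 HU noise and threshold
sensitivity ≤ 0.3% over a 40 HU range.  No automatic bottle detection or
partial-volume modelling is attempted.

## Numerical choices

- Working energy grid: 1 keV steps from 5 keV to the tube voltage;
  trapezoidal quadrature.
- Water reference fixed package-wide: H₂O, 998 kg/m³, M = 18.015 g/mol.
- Aluminum filter density 2699 kg/m³; default detector is the linear ramp
  D(E) = E (energy-integrating); a unity (photon-counting) response is
  provided.
- XCOM readers expect "total attenuation with coherent scattering" in
  cm²/g; conversion to m²/mol multiplies by 0.1 and the molar mass.
- Degenerate cases: zero RSS in the Gaussian BIC is floored at 1e-25 with
  a warning; zero-radius cylinders yield empty fills; an all-below
  threshold raises rather than returning an empty integral.
- No constraint (e.g. non-negativity) is imposed on the projected A; none
  proved necessary on the packaged data.

## Known limitations

- The synthetic physics is a two-component model (one photoelectric
  energy profile, one Compton profile), so its theoretical potency matrix
  has numerical rank 2; trailing theory singular values are exactly zero
  rather than merely small.
- Elements beyond Z = 20 (and K-edge physics generally) are unsupported.
- The air reference in predicted HU defaults to zero attenuation; the
  true-air option shifts predictions by ~0.1%.
- Vendor-proprietary phantom compositions ("solid water", tissue
  surrogates) are not packaged; only the six standard polymers with
  public formulas and densities are included.
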