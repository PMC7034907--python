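# Methods

## Attenuation model

Compound mass attenuation follows Bragg additivity,
µ/ρ(E) = Σᵢ wᵢ·(µ/ρ)ᵢ(E), with wᵢ the elemental mass fractions of the parsed
formula, and linear attenuation is µ = ρ·(µ/ρ). Per-element values come from
a bundled table of total mass attenuation coefficients (photoelectric +
incoherent + coherent) on the standard coarse tabulation grid
(10, 15, 20, 30, 40, 50, 60, 80, 100, 150, 200, 300, 400, 500 keV),
interpolated log-log linearly and never extrapolated. Log-log interpolation
on this grid is the standard treatment for smooth cross sections away from
absorption edges, and — relevant for reproducing published candidate
tables — it is also how such tables are conventionally computed, so the
package's values at 146.1 keV match published mineral µ values to a few
tenths of a percent.

Provenance of the bundled table: for the light elements that carry all
quantitative results (H, C, N, O, Na, Mg, Al, P, S, Cl, Ca, plus Fe, Cu) the
grid values are the standard published tabulations; water reproduces the
reference 0.1707 / 0.1505 cm²/g at 100 / 150 keV to <0.05%, which the test
suite asserts. The heavy-element columns (Ga, Mo, Gd, Lu) exist only to model
filters and scintillators in wide-band spectrum checks; they were computed
from Klein–Nishina incoherent scattering plus parametrised coherent and
photoelectric components anchored to published values, with explicit double
grid points at the K edges (Ga 10.4, Mo 20.0, Gd 50.2, Lu 63.3 keV). Expected
accuracy is ~0.5% for the light elements at 60–300 keV and ~5–10% for the
heavy columns, which only shifts simulated average detected energies by a
few keV — well inside the band tolerances used.

Hydration series (sodium carbonate 2.54→1.44 g/cm³, sodium sulphate
2.664→1.464 g/cm³) are evaluated only at their endpoints, each with its own
composition and density. Intermediate hydrate densities are *not*
interpolated — real hydrate densities are not linear in the water count — so
intermediate members need a user-supplied density. Trona's published density
range (2.11–2.17 g/cm³) is collapsed to its midpoint 2.14 by default,
matching the single published µ value; it is overridable.

## Beamline model

The source is the universal bending-magnet spectral shape
G₁(y) = y·∫_y^∞ K₅⁄₃(x) dx (evaluated by adaptive quadrature of the modified
Bessel function), photon flux per unit energy ∝ G₁(E/E_c)/E. The critical
energy defaults to E_c = 0.665·E²[GeV]·B[T] with 6.03 GeV and 0.85 T
(≈20.6 keV); the bending field is a configurable estimate, which is why
simulated average detected energies are treated as band checks
(the body-scan preset yields 135 keV against a nominal ~139 keV) rather than
calibration constants. Filters attenuate as exp(−Σµᵢtᵢ); the detector is
energy-integrating, weighting each energy by the scintillator's absorbed
fraction (1 − e^(−µ_sc·t)) times E. Light diffusion in the scintillator —
the stated reason measured effective energies exceed spectrum-simulated
ones — is deliberately not modelled; the reference-material calibration
supersedes the spectrum estimate, exactly as in practice. Default energy
grid: 10–400 keV in 0.5 keV steps, which resolves the filtered spectrum peak
at negligible cost.

Beam hardening is quantified as µ_eff(L) = −ln(Σ wᵢe^(−µᵢL))/L (the
spectrum-weighted mean µ at L = 0), computed with log-sum-exp for stability.
µ_eff is non-increasing in L for any spectrum; with the body-scan filtration
the µ_eff of water varies by ~0.2% over 0–6 cm (versus >60% unfiltered),
which is the quantitative content of "beam hardening is negligible".

## Calibration and classification

µ(E) of an edge-free material is strictly decreasing on 50–300 keV, so the
effective energy solves µ(reference, E) = µ_measured uniquely; the package
uses bracketed Brent root finding (energy tolerance 1e-6 keV, residual
checked against 1e-6 cm⁻¹) and reports the attainable µ interval when the
measurement is out of range. The reference is hydroxyapatite at the measured
bone-mineral density of 1.8 g/cm³ (deliberately the *bone* density, not the
~3.1 g/cm³ crystal density).

Candidate compatibility is interval intersection with a symmetric absolute
tolerance (default 0.01 cm⁻¹, ≈3% of the measured values): candidate
interval [µ_lo, µ_hi] versus measured interval [average − tol,
maximum + tol]. The rule is explicit and monotone — widening the tolerance
can only add candidates — and the verdict is "consistent with natron" as
soon as one candidate fits. Attenuation matching is necessarily
non-unique: any mineral with the right µ is "compatible"; the package makes
no chemical claim beyond that.

## Synthetic phantoms

`mummy_preset` emulates the imaging situation of the case study: a balm
matrix (generic organic composition with density chosen so µ ≈ 0.18 cm⁻¹ at
146.1 keV; the true balm µ is unknown and is a free parameter), one large
bone-like ellipsoid (hydroxyapatite, 1.8 g/cm³, µ ≈ 0.275 cm⁻¹), and 20
non-overlapping mineral spheres (10 halite + 10 nahcolite, radii 3–10
voxels) in a 96×112×112 grid at 24.37 µm voxels (the body-scan voxel size;
grid size chosen for desk-scale runtime). Degradation is a Gaussian PSF
(σ = 0.7 voxel, reflective boundaries so the volume mean is conserved)
followed by additive Gaussian noise on µ (σ = 0.01 cm⁻¹) — the standard
approximation for reconstructed synchrotron volumes; projection-domain
physics (photon statistics, phase contrast, ring artefacts) is out of scope
except for the stand-alone single-distance phase-retrieval operation, which
implements the homogeneous-object low-pass filter
1/(1 + πλD(δ/β)ν²) followed by −ln(·)/µ.

What passing synthetic tests does and does not show: the phantom shares the
real data's contrast regime, blur and noise scale, so it validates the
*chain* — calibration inversion, segmentation, interior statistics,
classification logic — end to end (generation energy recovered to ≪1 keV,
recall 1.0, per-material bias ~2–3×10⁻⁴ cm⁻¹, far below the noise σ). It
does not validate the cross sections against a real scanner, nor the
segmentation against real balm texture, reconstruction artefacts or
non-spherical inclusions.

## Segmentation choices

Inclusions are 26-connected components of {µ > threshold} (default
0.25 cm⁻¹, between balm ~0.18 and the minerals ~0.30), minimum size 27
voxels. Statistics use the erosion-by-1 interior (3³ structuring element) of
each component to suppress the partial-volume rim, falling back to the full
component when erosion empties it; centroids use the full component. Both
averaging conventions — unweighted mean of per-inclusion means and
voxel-weighted mean — are reported, since either could be meant by an
"average inclusion µ"; neither is privileged. Recovery scoring matches truth
to predictions greedily by centroid distance within twice the truth
inclusion's equivalent radius; unmatched predictions are false positives.

## Numerical and design notes

- Energy grid endpoints are treated as inside the tabulated range; anything
  beyond raises rather than extrapolates.
- Opaque filter stacks (detected weight exactly zero across the grid) raise
  a degenerate-spectrum error rather than returning NaNs.
- The Lu K edge at 63.3 keV sits inside the 50–300 keV working band, so
  scintillator monotonicity properties hold only above it; calibration
  references are restricted to edge-free materials, for which µ(E) is
  strictly monotone on the bracket.
- Phantom generation is fully deterministic given the seed (geometry from a
  seeded generator, clean voxel values exact material µ in float32);
  degradation takes an explicit seed.
- Pipeline configs are single YAML documents validated by explicit fail-fast
  resolution of every referenced material and preset; reports embed the
  resolved config, package version and seed, contain no timestamps, and
  replay bit-for-bit.

## Known limitations

- No absorption-edge physics below the tabulated double points, no energies
  below 10 keV, no fluorescence; heavy-element columns are approximate.
- The bending-magnet field (hence E_c) and filter purity are estimates;
  simulated average detected energies are indicative bands only.
- Attenuation at a single effective energy cannot distinguish minerals with
  coincident µ; hydration series spanning wide µ intervals are compatible
  with almost any plausible measurement, so the verdict should be read as
  "not excluded", with identification weight carried by the ensemble.
- Intermediate hydrates need user densities; balm composition is a stand-in.
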