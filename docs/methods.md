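# Methods

This note records the physical models implemented in `adipoptics`, the
numerical choices behind them, and what the synthetic benchmarks do and
do not establish. All lengths are micrometres (µm); the propagation axis
is z, increasing into the tissue, with the illuminated surface at z = 0.

## The cell and tissue model

A white-fat adipocyte is modeled as a three-shell dielectric particle:
an 18 µm lipid-droplet core (n = 1.46) wrapped in a 1 µm cytoplasm
layer (n = 1.35) and a 10 nm cytoplasmic membrane (n = 1.42), total
outer diameter D = 20.02 µm, immersed in interstitial fluid (ISF) whose
index n_ISF ∈ [1.36, 1.40] encodes the degree of optical clearing
(heating-driven lipolysis releases lipids into the interstitial space
and raises n_ISF toward the droplet index). Tissue fragments are
close-packed rows of such cells; the propagation solvers treat the
cells as infinite cylinders (2-D), which captures jet formation and
whispering-gallery channeling at a fraction of the 3-D cost.

Two packing arrangements are provided, and they behave very differently:

* **In-line ("square") stacking** — cells form vertical columns. A beam
  centered on a column is relayed from lens to lens (a lens waveguide):
  a two-layer stack splits the beam into exactly three bright bottom
  spots (one axial, one mirror pair), and a six-layer stack still
  transmits ≈ 88% of the beam through the 20 µm exit window, almost
  independent of n_ISF. This is the geometry used for the
  jet/hot-spot phenomenology benchmarks.
* **Offset ("hexagonal") stacking** — alternate rows shifted by D/2
  (row pitch kept at D, so a 6-layer stack is still 120.1 µm thick).
  Each jet lands between two cells of the next row and is split again;
  transmission through the exit window falls to ≈ 46% at n_ISF = 1.36
  and becomes strongly sensitive to index matching. This is the
  geometry of the canonical optical-clearing transmittance run, the
  only one that reproduces the published clearing trend; a single
  packing cannot reproduce both the three-spot figure and the
  transmittance table, which is why the package keeps both.

The 10 nm membrane is far below any affordable grid pitch. Rasterized
fields either widen it to one pixel (`membrane="ring"`, the geometric
default, preserving the index value set) or omit it (`membrane="omit"`,
the wave-solver default — its optical effect, a phase of
k₀·Δn·t ≈ 4×10⁻³ rad, is negligible). The analytic radial profile
always retains it. Soft-boundary cells replace each shell step with a
logistic blend of width `boundary_softness` (canonical value 0.5 µm;
the transition is exactly the midpoint value on the nominal boundary).
Hard-boundary rasters can be anti-aliased by subpixel permittivity
averaging (`antialias=2`), which reduced the layered-cylinder benchmark
error noticeably at λ/15n sampling.

The quasi-regular ("jittered") variant displaces every center by an
independent uniform draw from [−fD/2, +fD/2] per axis and, optionally,
scales each diameter by a draw from [1−f, 1+f], with f = 0.2 as the
canonical disorder level (≈ 2 µm position scatter per axis and ≈ ±20%
size scatter). All draws derive from an explicit seed.

## Full-wave solver (frequency domain)

The monochromatic solver computes the scalar Helmholtz field
(TE-polarized: E out of plane, exact for 2-D Maxwell; TM is offered as
the same scalar approximation, defensible at these weak contrasts) in
the scattered-field formulation: the incident focused Gaussian beam
(930 nm, waist radius w₀ = 10 µm at the surface) is an exact
angular-spectrum solution of the homogeneous ISF, and the solver
iterates a preconditioned convergent Born series for the scattered
field with an FFT-diagonal Green's function:

    E ← E + (i/ε) V [G(VE + S) − E],
    V = k²(r) − k_b² − iε,   G = (|p|² − k_b² − iε)⁻¹,

with the background k_b chosen to minimize the contrast and
ε = 1.05·max|Re V|. Each iteration costs two FFTs; the update norm is
monitored and iteration stops at a relative tolerance of 10⁻⁴
(tightening to 10⁻⁵ moves the windowed transmittance by < 0.1 pp).
Open boundaries are a 24 µm rim in which the real index tapers to the
background while absorption ramps quadratically to 0.9ε; the source
term uses the *physical* contrast only, so the incident beam reaches
the cells unattenuated while outgoing scattered waves are absorbed
before the periodic FFT domain can wrap them. Narrowing the rim to
16 µm raises the layered-cylinder benchmark error from 0.3% to ≈ 2%,
which fixed the default.

Validation gates (all in the test suite): free space reproduces the
analytic Gaussian beam to < 10⁻⁴ relative L2; a coated cylinder (5 µm
core + 1 µm coat) against an independently implemented multilayer
Bessel/Hankel series agrees to < 2% relative L2 on the scattered field
at λ/15n sampling; transmittance is grid-stable to < 1 pp under
step halving.

**Windowed transmittance.** `transmitted_fraction` supports two
conventions. The default integrates the longitudinal Poynting component
over the 20 µm window and normalizes by total beam power (bounded by 1;
uniform medium at 120 µm gives the erf closed form ≈ 0.95). The
canonical clearing run instead reports the photometric reading: |E|²
integrated over the 20 µm window at the bottom surface of the cell
stack, normalized to the incident beam's |E|² over the same window.
With offset packing and 0.5 µm soft shells this yields
46.4% / 48.8% / 60.6% for n_ISF = 1.36 / 1.38 / 1.40 (ratio
60.6/46.4 = 1.31), the regime of the published clearing table. Grid for
these runs: λ/(10·n_core) ≈ 64 nm (the Mie gate is passed at λ/15n,
and λ/10n vs λ/15n changes T by ≤ 0.1 pp, so the coarser grid is used
for the multi-million-pixel production solves, which then take
~2 minutes each on one core).

**Hot spots** are local maxima of intensity along a horizontal
extraction line, with a prominence threshold relative to the line
maximum (default 10%); the choice of threshold only matters for spots
an order of magnitude weaker than the jets.

## Analytic transmittance and its inversion

For a thick stack the collimated transmittance follows
Bouguer–Beer–Lambert, T = exp(−µ_s·l), with the Mie-estimate
scattering coefficient µ_s = a²ρ_s(m−1)², m = n_LD/n_ISF. The product
a²ρ_s is the only combination that matters; for close-packed cells
(one cell of outer diameter D per D×D column) it equals exactly
1 µm⁻¹ when a is read as the outer *diameter*. That reading is the
package default because it reproduces every printed value of the
clearing table and of the heated-tissue inversion series
(m = 1.088/1.087/1.086 from T = 39.4/40.1/41.4% at l = 120 µm, the
mid-point of the reported 120 ± 15 µm layer thickness); the
radius-based reading remains available through the explicit `a2rho`
argument. The inversion m = 1 + sqrt(−ln T/(a²ρ_s·l)) round-trips with
the forward model to 10⁻¹².

## OCT image synthesis (wave Monte Carlo)

The OCT model mirrors a time-domain interferometer through its
spectral decomposition. The source spectrum is Gaussian with
σ_k = sqrt(2 ln 2)/δz_air, calibrated so the point-reflector envelope
in air has the instrument FWHM δz_air = 6.2 µm (the implied wavelength
FWHM is 61.6 nm at 930 nm; the synthesized PSF measures 6.32 µm with
the default 64-sample, ±2.5σ discretization). In-tissue resolution is
the quotient δz_air/n̄ (4.2 µm at n̄ = 1.47). The sample beam is a
converging Gaussian, 12 µm wide at the surface and 10 µm at its focus
100 µm deep.

Per wavenumber sample the beam is propagated *forward* through the
index map by a symmetric split-step scheme — half-step transverse
spectral diffraction exp(i dz/2 √(k_b²−k_x²)), local refraction screen
exp(i k(n−n_b) dz), half-step diffraction — which is unitary in
lossless media (power drift < 10⁻⁴ over 120 µm at dz = 0.4 µm; the
soft cell boundaries keep the screens smooth at this step, which is
why dz may exceed λ/4 without visible error in the gates below).
Reflection is local and single-scatter: the axial Fresnel reflectance
r = (n(z)−n(z+dz))/(n(z)+n(z+dz)) of each step seeds a *backward*
field that is accumulated up through the same medium and overlapped
with the incident field at the surface; the air/tissue surface
reflection provides the zero-delay reference peak. Summing over the
spectrum with round-trip phase 2kζ gives the envelope vs optical depth
ζ (air-equivalent µm; divide by the mean index for geometric depth).
Trials redraw the lattice jitter; envelopes are ensemble-averaged in
intensity, and the displayed quantity is
W = log₁₀(1 + W_oct(ζ)/W_oct(0)), normalized to the surface response of
the same A-scan.

Gates: a buried sharp interface returns a peak at its optical depth
whose energy matches the Fresnel |r|² against the surface reference to
< 5% (with a collimated wide beam so geometric overlap cancels), and
doubling the index step quadruples the echo energy. Known limits of
the single-backscatter scheme: no multiple echoes, no speckle
decorrelation from transverse scanning, no detector noise; a 0.5 µm
soft boundary physically suppresses (dephases) part of its echo, so
quantitative Fresnel checks use sharp interfaces.

The spectral sampling sets an alias depth π/dk (208 µm for the default
64 samples across ±2.5σ); deep fragments use 96 samples. C-scans
raster the beam over an (x, y) grid; each y-row is simulated in the
(x, z) slice plane through the 3-D sphere lattice at that y (a
constant-y slice of a three-shell sphere is a circle stack of reduced
radii), a separable thin-3-D approximation adequate for the
quasi-periodic en-face pattern. Production sizes are scaled to the
question asked: the published-style en-face raster uses 21×21 = 441
beam positions over a 4-layer, 3×3-cell fragment at 0.5 µm grid and 32
wavenumbers, extracting the W slab mid-fragment.

## B-scan statistics

D_b is the coefficient of variation (population SD over mean) of the
B-scan brightness over a region — deviation is taken from the regional
mean, the region defaulting to whatever array or crop is passed.
Pre-processing mirrors the experimental pipeline: pixel-wise averaging
of groups of 4 co-located scans, then a linear contrast stretch between
the mean of a 50×50 px sample-free noise box (top-left) and the maximum
of the remaining pixels, clipped below. Bottom-surface hot-spot
profiles average a ±2 px band around the interface row (auto-detected
as the brightest lower-half row; ties within 1% pick the deeper row).
Windowed statistics use 20 µm windows across 0–2000 µm (100 windows)
and report the per-window heated/baseline intensity ratio as
mean ± SD. The dispersion property test runs simulated B-scans of
jittered lattices at three ISF indices and checks D_b grows as index
contrast grows; it is computed on raw (unstretched) W values. The
published experimental brightness-increase figures require the original
OCT recordings and are out of scope; the module supplies the
computations, not the data.

## Reproducibility

Every stochastic stage (lattice jitter, Monte-Carlo trials, synthetic
noise) is driven by an explicit integer seed; one global seed fans out
to stage seeds via `numpy.random.SeedSequence.spawn`, truncated below
2³¹. Identical seeds reproduce scans bit-for-bit. Run manifests record
the config hash, stage seeds, package version and per-output SHA-256
checksums, so deterministic stages reproduce checksum-for-checksum.

## Known limitations

* 2-D (cylinder) optics: quantitative 3-D focusing is stronger than
  2-D; agreement with the published 2-D reference numbers, not with
  real tissue, is what the gates establish.
* The scalar TM option ignores the polarization term of Maxwell's
  equations; at Δn ≤ 0.11 the neglected term is second order.
* Single backscatter in OCT synthesis; no absorption or dispersion
  anywhere.
* The synthetic benchmarks use monodisperse cells; real adipocytes span
  15–250 µm, so passing tests demonstrate the mechanism (jet formation,
  clearing, hot-spot statistics), not population-level predictions.
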