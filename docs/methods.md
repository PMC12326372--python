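# Methods

## Scope and model

`flavospin` analyses an S = 1/2 flavin semiquinone coupled to ring
nuclei with I = 1/2 or I = 1. The electron g tensor defaults to
(gX, gY, gZ) = (2.0043, 2.0036, 2.0022) with z normal to the
isoalloxazine plane; hyperfine (A) and quadrupole (Q) tensors are given
by principal values in MHz plus active z-y-z Euler angles relative to
the g frame, defaulting to collinear axes (the published tensor
orientations for this system are collinear with g to within the
resolution of the experiments). Every quadrupole tensor is required to
be traceless to 10⁻⁹ MHz at construction, so tracelessness holds by
construction everywhere downstream, including in the refinement grid
where the third principal value is always −(Q1+Q2).

Physical constants are CODATA 2018. The nuclear g factors are
gN(¹H) = 5.5856947, gN(¹³C) = 1.4048236, gN(¹⁴N) = 0.4037610,
gN(¹⁵N) = −0.5663796, giving gN(¹⁴N)/gN(¹⁵N) = −0.71289. Isotope
scaling of printed tensors uses the two-decimal factor 0.71 by default
("preserve-printed-sign" mode), because the conventional tabulated ¹⁴N
values round-trip only with the rounded factor and are quoted as
positive magnitudes despite the negative gN ratio; a "strict-sign" mode
applies the signed full-precision ratio for physical sign bookkeeping.
The absolute signs of hyperfine couplings relative to the gN sign
convention are not observable in these experiments; stored signs follow
the published convention.

## Nuclear frequencies

The default engine is the high-field (electron-manifold) approximation:
per manifold mS = ±1/2 the nucleus experiences the effective field
v = mS(n̂·A) − νL n̂ (MHz), and transition frequencies come from the
(2I+1)-dimensional sub-Hamiltonian v·I + I·Q·I. For I = 1/2 this is
|v|; for I = 1 the three eigenvalues give two single-quantum lines and
one double-quantum line per manifold (labels sq1, sq2, dq; frequencies
sorted descending, ties broken in that label order). At the canonical z
orientation of an I = 1 nucleus the single-quantum pair within one
manifold is split by exactly 3|Qz| — the in-plane asymmetry (Qx−Qy)/2
mixes only the mI = ±1 levels symmetrically, shifting both sq lines
equally — which is what the parallel-orientation ridge-pair analysis
exploits.

Validation: against brute-force diagonalisation of the full
2(2I+1)-dimensional electron-nuclear Hamiltonian (implemented
independently in the test suite), 1000 random systems with principal
values up to ±80 MHz, arbitrary orientations, |Q| ≤ 3 MHz and fields in
1200–1230 mT agree to < 0.5 % (I = 1/2) and < 1 % (I = 1). Relative
error is measured against the larger of the transition frequency and
the Larmor frequency, because lines near exact cancellation
(|A| ≈ 2νL) have arbitrarily small absolute frequency while the
absolute error stays at the ~A²/νe level (≲ 0.03 MHz at Q band).

First-order formulas (ν± = |A|/2 ± νL strong, νL ± |A|/2 weak) are kept
as a separate closed form for the ELDOR edge arithmetic; they agree
with the exact engine to < 10⁻⁶ MHz at canonical orientations of
collinear axial tensors. Second-order perturbation formulas are not
implemented — the sub-Hamiltonian diagonalisation supersedes them.

## Powder spectra and orientation selection

Orientations are sampled on one octant of the unit sphere (valid
because all tensor frames are collinear with g; a non-collinear system
would need the full sphere) with a deterministic golden-angle spiral:
cos θ uniform at midpoints, φ advancing by the golden angle modulo π/2,
equal quadrature weights. The powder average of P2(cos θ) vanishes to
< 10⁻³ already at 200 knots; CW spectra default to 3000 knots, at which
the outermost splitting of the fixtures is converged to < 0.05 mT.

Resonance fields are first order: B = hν/(g(n̂)μB) − C·Σj mI,j·|n̂·Aj|
with C = h/(ge μB). Sticks are accumulated over all nuclear projection
combinations and convolved with a Gaussian of FWHM 0.9 mT (default,
configurable; chosen so the wild-type fixture shows resolved
outermost ripples). The CW presentation is the numerical derivative of
the absorption lineshape, so the two modes are consistent by
construction. The outermost-shoulder analysis takes the lowest- and
highest-field local extrema of the derivative trace with |amplitude|
above 2 % of the maximum (threshold configurable; 2 % is robust on
synthetic spectra with a few percent amplitude noise).

Orientation-selection weights sum, over projection combinations, a
Gaussian of the resonance offset at the observer field with standard
deviation equal to the excitation bandwidth, normalised to maximum 1.
Bandwidth defaults: 42 MHz for HYSCORE/ESE-style excitation, 1 MHz for
the ELDOR HTA context. With these settings a high-field-tail observer
concentrates weight near the ring normal and a centre-field observer
favours in-plane orientations, matching the qualitative behaviour of
the excitation-pattern insets of the measured spectra.

## HYSCORE and ELDOR prediction

Cross-peaks pair every α-manifold frequency with every β-manifold
frequency of the same nucleus (sq–sq and sq–dq for I = 1; dq–dq is not
tracked). Quadrant assignment follows the coupling regime of the
secular component n̂·A·n̂: weak → (+,+), strong → (+,−). Intensities
are heuristic: orientation excitation weight times the ESEEM-style
modulation factor k = (νL·B_pseudo/(να·νβ))² capped at 1, where
B_pseudo is the component of n̂·A perpendicular to n̂. This factor
vanishes along hyperfine principal directions and for uncoupled nuclei
— the qualitative behaviour ELDOR-detected NMR requires — but it is not
a density-operator amplitude: τ-dependent blind spots and combination
lines are out of scope, and all quantitative conclusions rest on peak
positions, never intensities. Correlations involving a dq transition
get a fixed relative weight of 0.3 (the data do not resolve which ¹⁴N
ridges are sq vs dq, so dq pairs are kept but de-emphasised).

Anti-diagonal crossings: ridge points within 0.2 MHz perpendicular
distance of ν1 + ν2 = 2νL imply in-plane couplings |A⊥| = |ν1 − ν2|.
Because the weak-coupling ridge runs along the anti-diagonal to first
order, a contiguous crossing run wider than 0.4 MHz is reported by its
two extremes (the canonical-orientation crossings, i.e. the two
in-plane principal values); a narrow run (axial tensor) collapses to
its weighted mean.

## Inference pipeline

Stage estimates thread forward; each stage is a closed form or a grid
search (no gradient descent — the nearest-neighbour objective is
non-smooth, and the grid mirrors the one-at-a-time manual variation
used to quote uncertainties).

- CW: Az = (ΔB_labelled − ΔB_reference)/C, uncertainties in
  quadrature; a non-positive difference returns 0 with a
  "no broadening" flag.
- ELDOR edges: |Az| = edge_high + edge_low, with the consistency check
  (edge_high − edge_low) − 2νL; edge sums ≤ 2νL are flagged as
  weak-regime inputs.
- HYSCORE grid fit: objective = Σ over observed picks of the squared
  distance to the nearest predicted ridge point (predicted cloud pooled
  over observers and symmetrised in ν1/ν2). Grid steps 0.5 MHz for the
  parallel and 0.25 MHz for the perpendicular component: ridge
  positions are several times more sensitive to A⊥, so a coarser
  perpendicular grid would leak its rounding error into A∥. Grids are
  anchored at integer multiples of the step. Ties break toward the
  lexicographically smallest parameter vector.
- Uncertainties: one-at-a-time variation until the objective exceeds
  twice its optimum ("clearly not coincident", operationalised;
  threshold configurable), never reported below one grid step. On 20
  random noiseless axial systems the recovered values are unbiased to
  well under one grid step and every individual error lies inside its
  reported uncertainty; in flat objective valleys the interval widens
  accordingly rather than the point estimate being over-trusted.
- Quadrupole refinement: hyperfine fixed from isotope scaling;
  two-parameter grid (step 0.1 MHz) over (Q1, Q2) with Q3 from
  tracelessness. Ridge positions are exactly invariant under Q → −Q
  (the flip permutes the sq labels within each manifold), so the
  absolute sign is not determined by the data; the reported tensor is
  normalised so its largest-magnitude principal value is positive,
  which matches the published sign sets for both ring nitrogens.
  In-plane values are reported without x/y assignment.

## Synthetic data

The fixture catalog stores the published tensor sets: ¹³C(4a)
(−13.5, −9, +40) MHz (z last), ¹⁵N(5) (5.6, 5.6, 74), ¹⁵N(10)
(3.2, 3.2, 38), the ¹⁴N tensors scaled by 0.71, and quadrupoles
(−0.8, −1.0, +1.8) and (+2.4, −1.6, −0.8) MHz for N(5)/N(10). Two
entries are placeholders: the ¹³C(2) tensor (0.9, 0.9, 1.8) MHz
represents "smaller than 2 MHz" (only a bound is known), and the ¹H(5)
tensor (−10, −26, −40) MHz is a synthetic stand-in of
literature-typical magnitude whose |Az| ≈ 40 MHz makes the wild-type
outermost splitting come out at ≈ 7.1 mT; neither placeholder enters
any tensor estimate.

Protocols emulate the measurement settings: X-band CW at 9.714 GHz;
Q-band HYSCORE/ELDOR at the published observer fields. The nominal
Q-band frequency differs per protocol (34.15 GHz for the ¹⁵N runs,
34.264 GHz for the ¹³C/¹⁴N/ELDOR runs): observer fields are only
meaningful relative to each run's own line position, and these values
put the published fields at the published part of the line (high-field
tail vs absorption maximum) for the stated g tensor. Both are inside
the 34.1–35.5 GHz range of the instruments emulated.

The noise model is deliberately simple: i.i.d. Gaussian amplitude noise
(relative to the spectrum maximum) on 1D spectra, and isotropic
Gaussian jitter (MHz) on picked ridge coordinates, reproducible per
seed. Ridge "picking" keeps the strongest predicted peaks (≥ 2 % of the
maximum weight), thinned to 200 points. What passing tests show: the
estimators invert the forward model correctly under these conditions
and degrade gracefully with jitter (0.2 MHz jitter keeps the recovered
A∥(¹⁵N5) within the published ±3 MHz). What they do not show:
robustness to baseline drift, blind-spot suppression of ridge segments,
mis-picked artefact peaks, or intensity distortions — none of which the
generator emulates.

## Numerical choices and degenerate inputs

- Frequencies and couplings in MHz, fields in mT, angles in degrees.
- Orientation grids are deterministic for a given knot count; fits use
  the same default knot count (400) as the simulation layer so
  noiseless self-consistency is exact.
- Eigenvalue ties in the I = 1 sub-Hamiltonian are handled by sorting;
  degenerate (A = 0) nuclei produce peaks at (νL, νL) with zero weight.
- Observer fields outside the simulated line support yield all-zero
  orientation weights with a warning, and empty peak sets warn rather
  than raise.
- The ridge-map rasteriser deposits weights bilinearly (total intensity
  equals total peak weight), then applies a Gaussian blur and
  symmetrises across the diagonal.

## Known limitations

- Intensities everywhere are heuristic; only positions are
  quantitative. Time-domain four-pulse simulation (τ blind spots,
  phase cycling, apodisation) is explicitly out of scope.
- The octant orientation grid assumes tensor frames collinear with g;
  arbitrary Euler angles are supported by the frequency engines but the
  powder symmetry expansion is then approximate.
- S > 1/2, g strain, inter-radical couplings and nuclear-nuclear
  couplings are not modelled.
- The fitter assumes an axial hyperfine template (A⊥, A∥); the rhombic
  in-plane split of ¹³C(4a) is accessed through anti-diagonal crossing
  analysis rather than a three-parameter grid.
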