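# Methods

## Physical model

A three-beam MD event couples the reference reflection G, a secondary H and
the coupling reflection G−H.  For weak reference reflections
(|F_G| ≪ |F_H F_{G−H}|) the event's line-profile asymmetry in an azimuthal
scan is governed by the second-order dynamical term, whose sign depends only
on the excitation geometry g and the triplet phase invariant
Ψ = δ_H + δ_{G−H} − δ_G.  The package implements the asymmetry rule

    HL ⇔ g·cos Ψ > 0,    LH ⇔ g·cos Ψ < 0,

with an INDETERMINATE band |cos Ψ| < 0.05 (configurable): near Ψ = ±90° the
asymmetry is too weak to read.  The rule was cross-checked against the full
set of 28 observed silicon 222 events (azimuth, g, Ψ, label) tabulated in
the test suite.  Only the *type* of asymmetry is used, never its magnitude:
lattice coherence lengths vary between samples and would enter any
quantitative inversion.

The rule is not trusted when the event is Aufhellung-dominated.  The
classifier requires a diffracting secondary: |F_H| above ~1 e with
W = |F_H F_{G−H}| ≈ 0 (forbidden coupling) or |F_G|/W above a threshold
(default 10) gives a DIP; |F_G| ≪ W validates the rule; an extinct
secondary produces no observable feature at all.  A separate warning flags
events whose H or G−H Bragg angle is within 2° of 45°, where polarization
suppresses the second-order term.

## Structure factors

F(hkl, E) = Σ_sites Σ_components occ · [f0(s) + f′(E) + i f″(E)] ·
e^{−B s²} · e^{2πi h·r}, with s = 1/(2d) from the cell metric.  f0 is the
standard four-Gaussian Cromer–Mann sum; neutral-element coefficients and the
Cromer–Liberman f′/f″ data come from gemmi's embedded tables, and the ionic
sets the toolkit needs (Si4+, O1−, F1−, H1−) are embedded directly from the
same international tabulation.  Anomalous terms are linearly interpolated on
a per-species energy grid (2–30 keV, 20 eV steps by default) and are those
of the parent free atom (free-atom-core approximation for ions).  The label
"N3−" maps to the published F1− coefficients — the isoelectronic 10-electron
anion — because no nitride entry exists in the standard tabulation; this is
a documented stand-in shape, and any other unknown ion raises an error
rather than silently approximating.

Phases use the branch (−180°, 180°]; circular differences are reported in
[0°, 180°].  Amplitudes below 10⁻⁶ e are treated as vanishing and give
undefined (flagged, not raised) triplet phases.  Reflection-set enumeration
for model comparison uses the Laue group derived from the CIF symmetry
operators plus the Friedel inversion; generated models default to P1 +
Friedel.

## Scan geometry and conventions

Crystal Cartesian frame: a* along x, b* in the x–y plane (fixed package
convention).  With k∥ = −|G*|/2 and k⊥ = (1/λ² − |G*|²/4)^{1/2}, the
crossing condition reduces to cos(Φ − φ_H) = rhs (see the `mdgeom`
docstring); the entering branch (Φ = φ_H + arccos rhs) is g = −1 and the
exiting branch g = +1 under the clockwise-positive rotation convention with
G* toward the observer.  Φ = 0 is the azimuth at which the in-plane
projection of the chosen reference lattice direction points upstream.
Tangency (|rhs| = 1 within 10⁻⁸) yields a single event with g = 0 and a
NEAR_TANGENT flag.  The minimum excitation energy has the closed form
E_min = hc·(C² + |G*|²/4)^{1/2} with C = (|H*|² − G*·H*)/(2|H⊥|);
hc = 12.3984 keV·Å throughout.

Bragg-cone lines report ω as the incidence angle referred to the plane
normal to G*, so the reference reflection's own line is the horizontal
ω = θ_G; branch colours (g) are assigned at the ω = θ_G crossings.

Two derived geometric facts shape the symmetry analysis:

- The events of H and of G−H occur exactly 180° apart with the same g, so
  any pattern-symmetry statement presumes an event set closed under
  H ↦ G−H (enumerate out to |H*| = 2/λ).
- Events whose secondary reciprocal point lies *inside* the sphere of
  diameter G* (G*·H* > |H*|²) move against the usual tracking law
  sign(dΦ/dE) = g; such events are rare for the weak, low-order reference
  reflections the method favours, and the property tests assert the law
  outside that sphere and its reversal inside.

Pattern period and mirror positions are computed on the asymmetry-carrying
(non-dip) events.  The dip sub-pattern genuinely has lower symmetry: the
mirror image of a dip whose coupling reflection is forbidden can be the
crossing of an extinct secondary, which is invisible; including dips halves
the apparent symmetry of the silicon 222 pattern without changing its
observable peak structure.

## Asymmetry reading

Each isolated peak is fitted on log10 intensities with
A·exp(−(Φ−Φ0)²/2σ²) + a + b(Φ−Φ0), weighted by counting statistics
(σ_log10 I = 1/(√I ln 10)); the window is re-centred once to ±5σ.  Log base
10 is fixed so slopes are comparable across data sets.  b < 0 reads HL,
b > 0 LH; the reliability is σ_b/|b| and observations above the cutoff
(default 50%, also exposed at 40% for stricter comparisons) are rejected.
Zero/negative counts are floored at 0.5 before the log; windows with more
than 20% floored points are rejected.  Dips and overlapped peaks are never
asymmetry-read.  Peak detection runs on the residual over a rolling-median
baseline (1° window); maxima at least twice less prominent than a peak
whose window contains them are treated as that peak's shoulder structure,
minima inside a peak window are never reported as dips, and detections with
FWHM estimates above 1° are discarded as baseline undulations.  Default
matching tolerance between peaks and predicted events is 0.3°.

Offset correction maximizes peak–event matches on a 0.05° grid and refines
by the mean matched residual; offsets are reported modulo the period of the
predicted pattern, and ties within one match by non-equivalent offsets are
flagged ambiguous.

## Model grids and ACDs

Charge-transfer models give each donor hydrogen occupancy 1−x and make the
acceptor a composite (neutral, 1−x; ion, x) site, so effective factors are
exactly linear in x.  B interpolation sets B_n(z) = (1−z)⟨B⟩ + z·B_{0,n}
with ⟨B⟩ the model's current mean.  Grid generators compose charge transfer
first, then B interpolation.  ACD cells compare the predicted label with
the observed one; INDETERMINATE predictions are unresolvable, never
mismatches, and the compatible region is the set of grid points without any
mismatch.  An all-unresolvable ACD yields the full grid flagged
uninformative.

## Packaged toy structures and defaults

- Silicon: conventional diamond cell, a = 5.431 Å.  Bond-charge model:
  Si⁴⁺ Cromer–Mann factors at the 8 atomic sites (B = 0.4668 Å², the
  room-temperature value), plus 2 electrons scattering as two hydrogens at
  the midpoint of each of the 16 bonds per cell.  The bond-site
  B = 3.726 Å² represents the smearing of bonding charge and is calibrated
  so the model's reference amplitude is |F_222| = 6.5 e at 8 keV; the
  222-scan triplet phases are insensitive to this choice (Ψ of the 513
  event changes by < 0.05° over bond B from 0 to 4 Å²).  Electrons per
  bond (2, a covalent pair) and the placement fraction (0.5) are
  configurable.
- Mock amino cell: orthorhombic P1, 6.0 × 7.5 × 9.0 Å, an amino-like group
  (N + 3 H at ~1 Å) plus a carbonyl-like oxygen half a cell from the
  nitrogen along a.  The oxygen makes odd-h reflections nearly cancel so
  that their phases — and hence hundreds of triplet phases — genuinely flip
  with the transferred charge x; without it a single dominant scatterer
  pins every phase and no event is susceptible.  Literature-B endpoints:
  N 2.0, H 4.0–5.5, O 6.0 Å².

## Synthetic scans

The generator renders each event as a multiplicative factor on a slowly
drifting baseline (default 1000 counts, 2% sinusoidal drift over 45°): a
symmetric Gaussian core (FWHM 0.12°, peak height 3× baseline) plus a
Gaussian-derivative antisymmetric term of relative strength
0.35·|cos Ψ| with sign −sign(g cos Ψ), whose shoulders extend 3 core widths
— asymmetries reach far beyond the intrinsic width, as in measured
profiles.  The product peak_height × asym_strength × e^{−1/2} is kept
below 1 so the profile stays positive.  Aufhellung events render as 50%
dips; Poisson noise is applied last from one explicitly seeded generator.
The default baseline gives √1000 ≈ 32 SNR at the baseline, above the
SNR = 20 regime the recovery guarantees refer to.

This line shape is phenomenological.  It realizes the correct asymmetry
*sense* and magnitude ordering, not the dynamical-theory profile; passing
round-trip tests therefore demonstrates that detection, indexing, fitting
and label reading are unbiased and self-consistent, not that the package
reproduces physical MD intensities.  Real data additionally contain
instrument resolution effects, mosaicity-induced symmetrization and
radiation-damage drift that the generator does not emulate.

## Problem sizes and numerical choices

The test suite and the reproduction script enumerate the full silicon 222
revolution at 8 keV (~200 observable events), simulate 60°–360° scans at
5–10 mdeg steps, and run the statistical recovery suites at 100 seeds
(slope recovery, ACD parameter recovery on a 6 × 5 grid) — sizes chosen so
each suite completes in about a minute while leaving the binomial
assertions well-powered.  Analytic event azimuths agree with a brute-force
Ewald-crossing scan to 10⁻⁴ degrees; Ewald residuals of enumerated events
are verified below 10⁻⁹/λ; root-finding on azimuth coincidences brackets at
1 eV and refines with Brent's method to 10⁻⁹ keV.  Site merging after
symmetry expansion uses a 10⁻⁴ fractional tolerance; fractional coordinates
are normalized to [0, 1).

## Known limitations

- No n-beam dynamical intensity computation: the asymmetry rule is used as
  a sign rule only, and no absolute intensities, extinction or absorption
  corrections are produced.
- Isotropic displacement parameters only; no anharmonic or multipole
  charge-density models.
- Overlapped peaks are flagged and excluded, never deconvolved.
- The per-fit slope standard error from weighted least squares on
  log-transformed Poisson data is ~10–15% optimistic; reliability cutoffs
  are therefore slightly conservative in coverage terms.
- Ionic scattering factors are limited to the embedded species; unknown
  ions raise an error by design.
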