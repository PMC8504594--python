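# Methods

## Scope and model overview

`mammodose` simulates the mammographic dose chain at desk scale: an
x-ray tube model produces a binned energy spectrum, filtration shapes
it, a voxel phantom describes the compressed breast, and a photon
Monte Carlo deposits energy in its compartments.  The quantity of
interest is the mean glandular dose (MGD), tallied *directly* in a
phantom whose glandular and adipose tissues are separate geometric
compartments ("non-mixture"), with the conventional homogeneous blend
("mixture") available for comparison.  Everything is deterministic
given a seed.

## Photon interaction data

Per-element tables (H, Be, C, N, O, Na, Mg, Al, Si, P, S, Cl, Ar, K,
Ti, Rh, Ag, W) over 1–50 keV are packaged as plain-text files, one per
element, with photoelectric, incoherent, coherent, total and mass
energy-absorption columns in cm²/g.  They were generated once
(`tools/make_coefficient_tables.py`) from locally evaluated physics:
Cromer–Liberman anomalous scattering factors for photoabsorption, IT92
atomic form factors under Thomson scattering for the coherent channel,
Klein–Nishina weighted by a Waller–Hartree incoherent scattering
function `S(q,Z) ≈ Z − f(q)²/Z`, and an energy-absorption column built
from fluorescence-corrected photoabsorption plus the Klein–Nishina
energy-transfer moment.  Spot checks against standard reference
compilations (Al and dry air at 10/20/30 keV) agree to 0.3–3.5 %.

Mixtures use the mass-fraction additivity rule; interpolation is
log-log linear, which reproduces table nodes exactly and is standard
for photon cross sections away from edges.  The Rh, Ag K edges and W
L edges are explicit grid nodes so no interpolation segment straddles
an edge.  Energies outside 1–50 keV are an error, never an
extrapolation.  Compositions are renormalized to sum exactly to one
(the printed assay rows total 99.9–100.1 %).  Two deliberate
composition choices: the printer-filament assays (PLA, PC, WOOD) are
entered verbatim even though they list no hydrogen, and the
paddle/support "polycarbonate" uses stoichiometric C₁₆H₁₄O₃ since only
its density is published.

## Beam model

The continuum is a Kramers thick-target law, `N(E) ∝ Z (E₀−E)/E` per
0.1 keV bin, with two inherent-filtration factors: anode
self-filtration and the 0.5 mm Be window.  Self-filtration assumes
exponentially distributed bremsstrahlung production depths, giving an
escape factor `1/(1 + μ_W(E)·d_eff/sin θ_anode)`.  The effective depth
`d_eff = 0.256 µm` is **the model's only tuned constant**: it was
fixed once so the fully filtered rhodium beam reproduces the clinical
unit's measured HVL of 0.531 mm Al, and it is recorded in every run
log.  With that constant frozen, the silver-beam HVL is a genuine
prediction: the model gives 0.564 mm Al against the 0.548 mm Al
characterization (+2.9 %), with the correct ordering (Ag harder
than Rh).

Tungsten L lines at 8.397 / 9.672 / 11.286 keV with relative
intensities 100:80:30 carry 10 % of the post-inherent-filtration
fluence by default (the line-to-continuum split is not published; the
fraction is a configurable model parameter).  Additional filters
(0.06 mm Rh or Ag) and the 2 mm polycarbonate paddle are per-bin
Beer–Lambert factors, so filters compose and commute.  Air kerma is
`Σ Φ(E)·E·(μen/ρ)_air(E)` in relative units; the HVL search brackets
and bisects the added aluminum thickness to <10⁻⁴ mm and is invariant
under spectrum scaling.  The paddle is considered part of the clinical
beam when quoting HVL.

Known limitations: no heel effect, no tube ripple, no K lines (the W K
edge at 69.5 keV is out of reach at 28 kVp), and absolute fluence per
mAs is a calibration constant rather than a prediction.

## Phantom

The compressed breast is a semicircular-footprint slab: radius 8 cm at
the chest wall (footprint size is not published; this yields a
400–500 g compressed breast across the 4–5 cm thicknesses), 1 mm
voxels, a skin shell of all voxels whose centers lie within 1.5 mm of
the outer surface — one voxel thick at the default pitch, open at the
chest-wall plane.  Axes are in cm, origin at the chest-wall/support
corner, the beam travels along −z.

The gland is a paraboloid of revolution: apex at the nipple, axis
running to the chest wall at mid-thickness, radius
`r(y) = s·√(1 − y/y_apex)`.  The lateral scale `s` is solved by
bisection so the realized interior glandular **mass** fraction (skin
excluded) lands within ±1 % of the target; an unreachable target
raises a sizing error naming the achievable range.  "Glandular ratio"
is interpreted as a mass fraction, with a volume-fraction switch
available.  Masks are nested in the scale parameter, so the glandular
region grows monotonically with the target.

Mixture mode fills the interior with a single blend whose composition
is the mass-weighted average and whose density uses mass-weighted
specific volumes, `1/ρ = g/ρ_gl + (1−g)/ρ_ad`, conserving component
masses.

Six dosimeter positions mirror the physical phantoms' six holes: on
the chest-wall→nipple axis at mid-thickness, at evenly spaced
quantiles of the glandular extent, snapped to glandular voxel centers.

## Transport

Photon histories are tracked by delta (Woodcock) tracking against an
energy-dependent majorant over the materials present, so voxel
boundaries never require ray tracing.  Cross sections come from the
packaged tables pre-tabulated on a 0.02 keV grid.  At a real
collision:

* **photoelectric** — the full photon energy is deposited locally and
  the history ends (kerma approximation: photoelectron ranges at
  ≤28 keV are below the voxel pitch; fluorescence in low-Z tissue has
  <1 % yield and is neglected);
* **incoherent** — the scattering cosine is rejection-sampled from the
  free-electron Klein–Nishina law, the recoil energy deposited
  locally, and the photon continues; below 1 keV it is absorbed on the
  spot;
* **coherent** — direction changes by the Thomson angular law, a
  deliberate form-factor-free simplification (switchable off; the
  channel redirects without energy loss and its angular detail has
  little effect on broad-beam compartment tallies).

The geometry stack is compression paddle (2 mm polycarbonate) directly
on the phantom, support plate (default 5 mm polycarbonate — the
published 5 cm is implausible for a support plate and remains available
through configuration) directly below, air elsewhere in the bounding
box.  Photons start at the paddle surface; the source-to-paddle air
column is not tracked.  Source directions point from the focal spot
(65 cm above the breast, over the chest-wall midpoint) to points
sampled uniformly on the field rectangle clipped to the phantom
bounding box — a flat-field approximation of the uniform-solid-angle
law, adequate at the ≤10° half-angles involved.  A 10⁴-step livelock
guard deposits and terminates runaway histories, counting them in the
result.

Batches are independent by construction: batch *b* of a run with seed
*s* uses the PCG64 stream seeded by the sequence (s, b).  Tally results
are bit-reproducible for a given (seed, configuration, phantom).
Relative errors are the standard error of batch means over the batch
mean; zero-mean tallies report "undefined" rather than failing.
Point tallies accumulate deposits inside 1.5 mm spheres at the
dosimeter positions; at 10⁶ histories they carry ~20 % relative error
and are diagnostics, not part of the MGD.

## Dose analysis and the study

MGD per source photon is the glandular-compartment deposit over the
glandular mass (non-mixture), or the interior deposit over the
interior mass (mixture — the glandular fraction cancels between
energy share and mass share, which is precisely the design difference
the study probes).  Filter comparisons are made at equal tube loading
by weighting each cell with its filtered-beam fluence per mAs.

Absolute doses require the tube output in photons/(mAs·sr), which is
not published and which a Kramers-type model cannot predict.  The
study therefore anchors exactly one cell — 4 cm / 50 % / Ag at the
published 0.98 mGy — fixing that constant (recorded in the run log)
and leaving the other 17 cells as predictions.  In the packaged
configuration those predictions land within ±8 % of the published
per-thickness means, inside the ±30 % band considered meaningful for a
single-anchor semi-empirical model.

The full study runs 18 cells (3 thicknesses × 3 glandularities × 2
filters; 36 with the mixture companion) with deterministic per-cell
seeds derived from a master seed, checks each cell against the 2 %
relative-error ceiling (flagging, not failing), and derives: per-filter
and per-thickness means, the Ag-vs-Rh excess per phantom and averaged,
the 25→75 % glandularity trends in both modes, thickness monotonicity,
and deltas against the published fixture doses.  The published
simulated-vs-measured discrepancy is quoted in the source at both
"~15 %" and "within ~5 %"; the report recomputes the number from the
printed values (≈1 % on average, ≤3.5 % per row) and shows it beside
both published framings rather than adjudicating.

## Problem sizes and reproducibility

The packaged default is 10⁶ histories per cell in 20 batches, chosen as
the point where the glandular-tally relative error (~0.1–0.2 %) is far
below the 2 % contract while the whole 18-cell grid completes in under
a minute on one CPU; the reference study scale of 10⁸ histories changes
only the statistical error.  All random draws in a study descend from
the single master seed.

## What the simulated conditions do and do not show

The phantom is a geometric idealization: no ductal branching, no
pectoral muscle, no compression mechanics, and a footprint chosen for
plausible mass rather than taken from a subject.  Results that depend
on absolute mass or absolute output (mGy values) are therefore
model-relative predictions after single-cell anchoring, while ratios —
filter excess, thickness and glandularity trends, relative errors —
are the quantities the model can genuinely test.  Two published
observations are not reproduced quantitatively by this model chain and
are reported as such: the silver-beam HVL comes out 2.9 % above its
0.548 mm Al characterization, the Ag-vs-Rh excess averages ~28 %
against the published 30–40 % band, and the non-mixture glandularity
trend is flat-to-slightly-positive (+0.2 ± 0.1 %) rather than the
published ~10 % decrease — the published account itself is mixed on
the last point, describing per-thickness simulated doses that
*increase* slightly with glandularity at 4.5 and 5 cm.  The robust
qualitative contrast the model does reproduce is that the mixture
phantom's trend is clearly positive while the separate-compartment
phantom's is near zero.
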