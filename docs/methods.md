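# Methods

This package models the current spread of sacral nerve stimulation (SNS)
and its effect on nearby myelinated fibres.  The chain has four stages:
a labelled tissue volume, implanted hardware geometry, a quasi-static
field solve, and a population of double-cable axon models whose 1:1
firing defines the volume of tissue activated (VTA).  This note records
the model assumptions, the numerical choices, and what the synthetic
anatomy does and does not stand in for.

## Tissue volume

The field model needs a labelled voxel volume with per-label
conductivity.  The anatomy the pipeline was designed around — a pelvic
segmentation with fat background, sacrum and rectum — is represented by
a parametric generator (`snsvta.anatomy.make_synthetic_pelvis`):

* overall extent 150 × 150 × 120 mm at 1.15 mm isotropic voxels
  (echoing the in-plane resolution of the clinical T2 imaging such
  models are segmented from);
* a bone slab of thickness 27.3 mm (seven 3.9 mm slices) pierced by
  four cylindrical foramen channels (8 mm diameter, vertically spaced
  like the S1–S4 foramina, centres jittered ±1 mm by the seed);
* a colon tube (radius 12 mm) running vertically anterior to the slab,
  its path perturbed by the seed;
* conductivities at the stimulation frequency: fat 0.01 S/m (also the
  background "pelvis" tissue), bone 0.02 S/m, colon 0.01 S/m.  The
  foramen channel interiors revert to fat (their true content — nerve,
  vessels, connective tissue — is not modelled; the value is
  configurable).

`make_homogeneous` produces the control volume: fat conductivity
everywhere, same extent.

The generator is *parametric, not anatomically registered*: channel
positions, slab extent and rectum path are plausible dimensions, not a
patient geometry.  Percent-activation values computed on it therefore
carry the ±10-point tolerance used in the acceptance suite, and passing
those checks demonstrates that the modelling chain reproduces the
*contrasts and orderings* between stimulation settings, not that it
predicts a particular patient's percentages.

`contours_to_volume` reproduces the other half of a segmentation
workflow: hand-drawn per-slice contours lofted into a solid.  Slices
are rasterised to signed distance fields and linearly blended between
slice centres (with half-slice end caps), a deterministic, testable
analogue of proprietary CAD lofting.  Voxel membership everywhere in
the package is by voxel-centre-inside test; the error is bounded by one
voxel at each boundary and vanishes under refinement (tested at
1.0 → 0.5 mm).

## Hardware

Two quadripolar leads are modelled (contact 0 tip-most): model 3093
(contacts 3.0/10.2/3.0/3.0 mm, 1.5 mm gaps) and model 3889 (four 3.0 mm
contacts, 3.0 mm gaps), both 1.27 mm in diameter.  The distance from
the physical tip to contact 0 is not part of the published geometry;
the default is 1.5 mm and configurable.  The IPG is a 55 × 60 × 10 mm
cuboid placed posterior to the lead in the fat; it is the anodic return
in monopolar mode and an insulator otherwise.  The default placement
threads the lead along +x through the second foramen channel with the
tip at x = 50 mm, so the contact array spans the channel; this stands
in for the ideal parallel-to-nerve trajectory.

## Field solve

The potential obeys ∇·σ∇V = 0 (purely resistive quasi-static
approximation; at 14 Hz capacitive and dispersive effects are
neglected and σ is real).  Discretisation is a 7-point finite-volume
stencil on the voxel grid with harmonic-mean face conductances — chosen
over tetrahedral FEM because it is deterministic, mesh-free, respects
the discrete maximum principle, and can be verified against closed-form
solutions (the concentric-spheres oracle in the test suite, matched
within 5%).  Boundary conditions: cathode voxels Dirichlet at
−amplitude, anode voxels at 0 V (constant-voltage stimulation fixes
only the difference; the return is taken as reference), zero flux on
insulator surfaces and on the outer boundary of the volume.  Insulators
are zero-conductance voxels, i.e. their faces carry no current, which
is the natural Neumann condition on a staircase surface.  Driven
contact voxels are treated as metal (1 S/m) so the Dirichlet surface
couples to tissue with the full tissue conductance.

The linear system is solved by conjugate gradients with Jacobi
preconditioning from a zero initial guess, relative tolerance 1e-8 —
deterministic to the bit for a given grid.  At the default 1.15 mm grid
(1.7 M unknowns) a solve takes on the order of a minute on one core.
The discrete maximum principle (all potentials within the Dirichlet
range) is asserted on every solve.  Potentials inside hardware voxels
are undefined by the PDE; they are filled by repeated neighbour
averaging purely so that trilinear interpolation near the lead surface
has no artificial jumps.

A deliberate consequence of the voxel discretisation is that the
1.27 mm lead is one voxel wide at the default grid: its cross-sectional
area (1.32 mm²) approximates the true 1.27 mm² circle, but sub-voxel
surface detail is absent.  The 0.5 mm refinement option exists for
convergence studies (the −0.2 V isopotential volume decreases its
relative increment under refinement, as tested).

## Axon model

Fibres are double-cable myelinated axons of the published 5.7 µm
parameter class: explicit nodes of Ranvier (fast Na, persistent Na,
slow K, linear leak), MYSA and FLUT paranodes and six STIN internodal
segments per 0.5 mm internode, with the myelin sheath as a second
electrical layer over the axolemma coupled through the periaxonal
space.  The full parameter table ships as
`snsvta/data/mrg_fiber_5p7um.yaml` (geometry, densities, kinetics with
their Q10 scalings to 36 °C; rest −80 mV).  A 100 mm fibre has 201
nodes and 2201 compartments.

Extracellular coupling uses the standard two-layer cable formulation:
the unit-drive potential sampled at compartment centres enters through
axial difference terms scaled by the pulse train (equivalently, the
activating function drives the axolemma).  The stimulus is a monophasic
cathodic square pulse train at 14 Hz, 1 V drive.  The pulse width is
not part of the published setting; the default is 0.21 ms (the common
clinical SNS pulse width) and configurable.

Integration is backward Euler on the 2×2-block tridiagonal system
(block Thomas elimination, numba-compiled), with nodal gating advanced
by an exact exponential update using tabulated rate integrals — so each
step solves a linear system and is unconditionally stable.  Time
stepping uses dt = 0.005 ms inside a 15 ms window after each pulse
onset and dt = 0.05 ms through the quiet inter-pulse gaps, where the
membrane is passive and within microvolts of rest; the windowed plan
integrates the full train honestly (slow-gate recovery between pulses
is resolved) at about a quarter of the uniform-dt cost.  The
integrator was validated against an independent stiff-ODE solution
(scipy BDF) of the same equations: peak potentials agree to
~0.02 mV.  The simulated resting state is equilibrated for 300 ms and
cached; drift is below 0.1 mV over 50 ms.

Spike detection: upward crossing of −20 mV at the node 10 nodes from
the distal end (away from sealed-end effects), 1 ms lockout.  A fibre
is *activated* when it fires exactly once per pulse (1:1) over the
train.  Thresholds are found by doubling a small bracket upward and
bisecting; the search starts low because very strong fields block
conduction through depolarising inactivation, so "threshold" means the
lowest 1:1 amplitude.  With this parameter set the propagating action
potential at mid-fibre nodes overshoots to ≈ 0 mV (≈ +15 mV near
sealed ends); conduction velocity is ≈ 30 m/s, in the physiological
range for a 5.7 µm fibre.

Trains of three pulses use a duration of 214 ms: the fourth onset of a
14 Hz train falls at 214.3 ms, so a 215 ms window would contain a
fourth pulse whose spike cannot land before the window closes and
would spuriously break every 1:1 outcome.  The 1:1 criterion is
duration-invariant for a periodic drive (verified 3 vs 14 pulses), so
three-pulse trains are used as the scaled-down stand-in for 1000 ms
trains throughout the analysis scripts and tests.

## VTA and percent activation

Forty 100 mm fibres run parallel to the lead in four rows of ten
(superior/inferior/lateral/medial), 0.5 mm apart.  The lead-surface to
first-row clearance is not part of the published arrangement; default
1.0 mm, configurable and echoed in all outputs.  Axon midpoints align
with the midpoint of the driven contact span.  Percent activation is
100 × (activated fibres)/40, quantised at 2.5 points.  The VTA raster
places one fibre per transverse offset (default ±5 mm at 0.5 mm) and
is written with the white = 1:1 firing convention.

## Problem sizes used in tests and scripts

The test suite and acceptance script use the full 12-setting sweep at
the default 1.15 mm grid with three-pulse trains (the duration
invariance above justifies the shorter train), short 30–40 mm fibres
for axon-level oracles (the recording node stays 10 nodes from the
end), and small homogeneous boxes for solver and VTA property tests.

## Anatomical vs homogeneous percentages

Whether a published per-setting activation table of this kind reflects
the anatomical or the homogeneous variant of a model is often
under-specified, so `analysis/03_activation_sweep.py` computes the
12-setting sweep on both volumes.  The two differ in a characteristic
way: on the homogeneous control every 3 mm contact sees an identical
environment and the monopolar percentages are nearly uniform across
contacts (only the long contact drops), whereas on the synthetic pelvis
the contacts that sit inside the foramen channel — surrounded by the
more conductive bone — activate systematically fewer fibres than the
tip contact in open fat.  Absolute percentages on the synthetic volume
are therefore dominated by contact *position* relative to the channel,
a geometric feature of this particular parametric stand-in; the
contact-length and polarity contrasts (the quantities the acceptance
script reports) are directionally stable across both volumes.

## Known limitations

* The synthetic anatomy is a geometric stand-in; absolute
  percent-activation levels are sensitive to the unpublished clearance,
  pulse width and local tissue around each contact, which is why
  acceptance comparisons use ±10-point bands and emphasise orderings.
* Purely resistive tissue: no electrode–electrolyte interface, no
  capacitive or dispersive conductivity, no encapsulation layer.
* Single fibre diameter (5.7 µm); no diameter distributions, branching,
  or reflex circuitry — fibres are unconnected straight axons.
* Staircase hardware surfaces at voxel resolution; no partial-volume
  weighting.
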