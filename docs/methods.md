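# Methods

`cordstim` couples a quasi-static anisotropic volume-conductor model of
the lower-thoracic spine to nonlinear cable models of myelinated
dorsal-column (DC) and dorsal-root (DR) fibers, and derives stimulation
efficiency and selectivity metrics for extradural and intradural
electrode placements. This note records the model, its assumptions, the
numerical choices, and what the shipped tests do and do not demonstrate.

## Coordinate convention

Right-handed, millimetres: `x` mediolateral (+ left), `y` ventrodorsal
(+ dorsal), `z` rostrocaudal (+ rostral). The origin is the dural-sac
centre at the level of the stimulating cathode; the cord axis is
parallel to `z`. Angles about `z` are negative clockwise viewed from
rostral.

## Volume conductor

The spine segment (12 vertebrae with interposed discs, an elliptical
dural sac and an elliptical cord inside a 100 x 100 x 300 mm soft-tissue
prism) is a parametric idealisation: the five patient fixtures supply
the measured cord and CSF-space diameters and the cord position within
the sac ("ventral" places the cord centre twice as far from the dorsal
interior dura surface as from the ventral one, i.e. at -b/3 for inner
semi-axis b). The grey-matter butterfly is a union of ellipse lobes (two
dorsal and two ventral horns plus a central bridge) scaled to the cord
cross-section; the dorsomedial white-matter band — the territory of the
DC fibers — is the region between the cord surface and the dorsal
horns. Vertebral geometry is a fixed average-adult parameter set (22 mm
bodies, 6 mm discs, elliptical canal); it does not vary across patients.

Tissues are purely resistive. White matter is anisotropic (0.60 S/m
longitudinal along `z`, 0.083 S/m transverse); all other tissues are
isotropic with the standard literature values shipped in
`cordstim/data/conductivities.yaml` (CSF 1.8, grey matter 0.23, dura
0.030, extradural space 0.20, bone 0.02, disc 0.65, muscle 0.20 S/m).

Two geometric parameters the source measurements do not constrain are
fixture defaults: the dura thickness (0.3 mm, the value used throughout
the SCS modelling literature) and the dorsal extradural gap between
dura and canal wall (4 mm, wide enough for every catalogued electrode
at 1 mm clearance).

**Thin-dura representation.** A 0.3 mm membrane cannot be resolved by
affordable voxels, so the dura is represented as a 0.9 mm shell whose
conductivity is scaled by the thickness ratio (to 0.090 S/m). This
preserves the radial (trans-dural) resistance t/sigma exactly; it
overestimates the tangential dura conductance, which is negligible
beside the CSF pathway (< 1 % of the intrathecal longitudinal
conductance).

## Field solver

Laplace's equation `div(sigma grad Phi) = 0` is discretized with a
cell-centred finite-volume scheme on a graded rectilinear grid: face
conductances are distance-weighted harmonic means of the cell
conductivity tensors, so discrete current is conserved exactly (anode
and cathode currents balance to solver precision). Contacts are
Dirichlet cells (+1 V anodes, -1 V cathode; monopolar runs drive one
contact at 1 V against a grounded prism surface), the carrier is
insulating, and the outer boundary is insulating for bipolar/tripolar
runs. The SPD system is solved by Jacobi-preconditioned conjugate
gradients to a relative residual of 1e-8, far below the physical error
budget. Applied current is the surface integral of normal current
density over the anodic contacts; access resistance R_a is the
anode-cathode voltage over that current; stimulus fields at any
amplitude are scalar multiples of the unit solve.

Three discretization details matter and are part of the method:

1. **Interface snapping.** Grid edges are forced onto the contact
   z-boundaries and the extremal x/y coordinates of the cord, inner
   dura and outer dura ellipses. Without this, the contact length
   quantizes differently at each refinement level and the two lobes of
   the bipolar field shift against each other by several percent.
2. **Sub-cell homogenization.** Each cell's conductivity tensor is
   assembled from a 4 x 4 transverse sub-lattice: harmonic averaging
   along each axis, arithmetic across it (the resistor-network limit,
   correct for layered interfaces in either orientation). Centroid
   labelling was tried first and converges too slowly across the curved
   CSF/cord and dura interfaces.
3. **Contact-area correction.** Faces between contact metal and tissue
   are scaled so the total discrete contact surface equals the analytic
   lateral area; a voxelized cylinder otherwise exposes up to 4/pi more
   surface and biases R_a low by ~15-25 %. Azimuthal-arc contacts are
   shells on the shaft surface over an insulating core (full wedges
   would meet, and short, at the axis).

**Mesh profiles.** `MeshControl.coarse()` (~2e5 cells on a patient
model) is the survey resolution used for ratio and ordering metrics;
`MeshControl.coarse_contact()` adds a 0.2 mm near field, required for
designs with sub-millimetre contact structure (azimuthal arcs, paddle
columns); `MeshControl.fine()` (~1.4e6 cells) is the production
resolution chosen by the convergence protocol. The fine profile keeps
the 1.5 mm z spacing over the entire intrathecal channel (+-80 mm):
the dural sac, wrapped by low-conductivity dura and vertebral bone,
behaves as a leaky transmission line with a space constant of tens of
millimetres, and an under-resolved far tail feeds back into the channel
potential everywhere.

**Convergence protocol.** The production ladder is
`[fine x 1.25, fine x 1.0]`. Refining across it changes fiber-sampled
potentials by ~0.7 % and R_a by ~1 %. The error metric is the mean
absolute relative difference between levels, normalised per fiber by
that fiber's peak |Phi| (pointwise division by |Phi| is undefined at
the zero crossing of a bipolar field) and averaged over fibers. Beyond
this ladder the voxel footprint of the 1.1 mm cylindrical contact
changes discretely between levels and the inter-level error is no
longer monotone (2-3 %); this is the stated limitation of the voxel
discretization. Doubling the tissue-prism volume (all dimensions x
2^(1/3)) at fixed interior resolution changes fiber-sampled potentials
by ~2.6 % — a converged, genuinely physical sensitivity of this
geometry family to the prism margin — while thresholds move < 0.3 %,
which is the functionally relevant insensitivity.

## Axon models

Two myelinated-fiber membrane models are implemented, both driven by
extracellular potentials sampled at compartment centres along their
3-D trajectories:

* **SW**: nodes of Ranvier with CRRSS mammalian kinetics (fast sodium
  m^2 h and leak; gNa 1445 mS/cm^2, gL 128 mS/cm^2, Cm 2.5 uF/cm^2,
  37 C) joined by internodal axoplasmic resistance under perfectly
  insulating myelin. Geometry rules: axon diameter 0.6 D, node length
  1.5 um, internode length 100 D.
* **MRG**: the double-cable fiber. Nodes carry fast and persistent
  sodium, slow potassium and leak; MYSA/FLUT/STIN internodal sections
  have a passive axolemma beneath a finite-impedance myelin sheath
  (0.1 uF/cm^2 and 1 mS/cm^2 per lamella membrane) with a periaxonal
  conduction pathway; 36 C. Diameter-dependent geometry comes from the
  published table (5.7-16 um); the 3-15 um study diameters are linear
  inter-/extrapolations of that table, and the 3 um fiber in
  particular lies well below the table's range — its absolute
  thresholds should be read as qualitative.

The leak reversal of each model is calibrated once at initialisation so
that the stated resting potential (-80 mV) is an exact fixed point of
the unstimulated dynamics; an unstimulated 10 ms integration drifts by
less than 1e-10 mV.

**Integration.** theta-weighted trapezoidal stepping (theta = 0.5,
Crank-Nicolson) of the banded cable system — bandwidth 1 for SW,
bandwidth 3 for the interleaved (Vm, periaxonal) MRG layout, with the
nodal periaxonal space shorted to extracellular — and Rush-Larsen
exponential updates of the gating variables, whose rate laws are
evaluated on a [-200, +100] mV clamped voltage (outside that window
the gates are pinned at their limits and the raw exponentials
degenerate). Fibers are integrated in batches as one block-diagonal
banded system. The default step of 5 us is set by the dt-convergence
rule: halving it changes bisection thresholds by < 1 % (with this
scheme they change by < 0.1 %), and conduction velocities agree with a
0.5 us brute-force integration within 5 %. Backward Euler was rejected:
at 5 us it damps conduction velocity by ~13 %.

**Activation criterion.** A fiber counts as activated when its membrane
voltage crosses 0 mV with positive slope at both recording nodes, one
internode in from either fiber end — a propagating action potential,
not a local depolarization. The compartment grid is aligned so a node
of Ranvier lies at the trajectory point closest to the cathode (the
conservative, lowest-threshold convention). The default observation
window is the 300 us pulse plus 2 ms; scenario configurations may
shorten it when the fiber span and conduction velocity guarantee
earlier arrival (the shipped survey scenarios use 1.5 ms for 50 mm
spans at 9 um).

## Fiber populations

The dorsomedial band is split per side into 11 equal-width mediolateral
laminae named medial-to-lateral S5, S4, S3, S2, S1, L5, L4, L3, L2, L1
and the dorsal-root entry zone. The default population is the study
condition: 10 DC fibers per side in each of the 10 medial laminae (200
DC fibers on a uniform mediolateral x depth grid, optional seeded
jitter) plus 200 lateral-most fibers, each continuous with a DR fiber.
DR trajectories leave the dorsal cord at a 45 degree ventrolateral
inclination, descend through the CSF roughly one vertebral level (entry
stations staggered over 14 mm), pierce the dura laterally and end a few
millimetres beyond it in the foramen region; the path is a cubic-spline
resampling of the control polyline, tangent-continuous, and crosses the
white-matter/CSF boundary and the dura exactly once each. Distal DR
collaterals and branching Aβ collaterals are not modelled (absolute DC
thresholds are therefore overestimates).

Metric conventions: DC_0/DC_X treat the 200 medial-lamina fibers as the
DC population and the root fibers as the DR population (the entry-zone
fibers are electrically continuous with the roots); the power metric
uses whatever DC table a scenario passes, by default the medial set.
Fibers span the full model length by default; survey scenarios shorten
them (50-70 mm) to bound integration cost.

## Metrics

Per-fiber threshold amplitudes are found by bisection on the base-field
scalar to a relative error of 1 % (bracket by geometric doubling, then
interval halving; fibers that fail to activate at the amplitude cap are
recorded with an "inexcitable" sentinel). Threshold voltage is the
scalar times the anode-cathode drive (2 V for the unit bipole);
threshold current is threshold voltage over R_a; average pulse power
for the rectangular pulse is V^2 / R_a. DC_0 is the percentage of DC
fibers strictly below the lowest DR threshold (a tie is not selective);
the DC_X curve is evaluated at the sorted union of all thresholds,
exactly. The dermatome report finds the smallest amplitude at which
every target dermatome (default L2-L5) has an active fiber and lists
the non-target dermatomes co-activated at it. The clinical-matching
rule translates a report of N dermatome-sides of paresthesia into an
expected 5N % DC activation and returns the fiber diameter whose
activation at the clinical current is nearest; ties are flagged
ambiguous.

## What the tests show — and what they do not

The shipped suite verifies the solver against closed forms (slab exact;
concentric spheres and a point source within stated tolerances),
bisection against brute-force sweeps, cable physiology against
qualitative physiological orderings (diameter and pulse-width
monotonicity, SW > MRG thresholds, conduction velocities), and the
study-level claims at survey resolution: >= 90 % intradural power
reduction, >= 85 % R_a drop, > 5-fold threshold ratios, midline-maximal
DC_0, intradural >= extradural DC_0, and monotone degradation of the
azimuthal tripole's selectivity under rotation. Absolute access
resistances reproduce the reported values to within ~20-25 % — the
commercial contact dimensions behind the reported numbers are fixture
defaults here, and the residual is attributed to contact-geometry
detail, not tuned away. All of this concerns the idealised elliptical
geometry; none of it demonstrates accuracy for a real, MRI-derived
anatomy, for capacitive or electrode-interface effects (all tissues are
purely resistive), or for the absolute excitability of small-diameter
fibers whose MRG geometry is extrapolated.
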