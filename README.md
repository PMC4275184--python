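# cordstim

Patient-specific computational modelling of spinal cord stimulation
(SCS): an anisotropic volume-conductor field solver over a parametric
spine geometry coupled to nonlinear myelinated-axon cable models of
dorsal-column (DC) and dorsal-root (DR) fibers. The package quantifies
stimulation **efficiency** (access resistance R_a, average pulse power)
and **selectivity** (DC_0 / DC_X, dermatome recruitment) of extradural
versus intradural electrode placements and of different tripolar
electrode designs.

It is written for neural-engineering researchers studying SCS lead
design and placement. Five patient geometry fixtures (cord and
CSF-space diameters measured on transverse MRI, and the cord position
within the dural sac) ship with the package, along with a tissue
conductivity table and a catalogue of six electrode designs: a
three-contact percutaneous array, longitudinal tripoles (LT-1.5, LT-6),
transverse paddle tripoles (TT-1, TT-3) and an azimuthal tripole (AT)
with arc contacts at distinct angles around a percutaneous shaft.

## Model

The electric potential in the tissue solves the quasi-static Laplace
equation with a diagonal, cord-aligned conductivity tensor,

    div( sigma grad Phi ) = 0,

with Dirichlet contacts (+1 V anodes, −1 V cathode; the outer boundary
is insulating for bipolar/tripolar drive) discretized by a
conservative finite-volume scheme on a graded rectilinear grid. The
applied current I is the integral of normal current density over the
anodic contacts, R_a = (V_anode − V_cathode)/I, and the field at any
stimulus amplitude is a scalar multiple of the unit solve.

Fiber responses to a 300 µs monophasic rectangular pulse are computed
with two classic cable models — the SW (CRRSS) node-and-internode
model with perfectly insulating myelin, and the MRG double-cable model
with explicit paranodes, finite-impedance myelin and a periaxonal
pathway — integrated by a Crank–Nicolson banded solver batched over
whole fiber populations. A fiber's threshold is the smallest amplitude
(bisection, <1 % relative error) that elicits an action potential
propagating to both fiber ends. From per-fiber thresholds the package
derives input–output curves, average pulse power V²/R_a at a target
activation fraction, the selectivity metrics DC_0 (percent of DC
fibers recruitable with zero DR fibers active) and DC_X, and
per-dermatome recruitment reports.

See `docs/methods.md` for assumptions, parameter provenance, numerical
choices and limitations.

## Worked example

Survey-resolution comparison of the percutaneous array extradurally
(1 mm above the dura) versus intradurally (1 mm above the cord) on the
Patient-2 geometry, with a reduced population of 40 DC + 10 DR fibers
(9 µm, MRG). With `survey.yaml` containing

```yaml
patient: patient_2
design: ADTECH
mode: bipolar
mesh: coarse
n_dc_per_lamina: 2
n_dr_per_side: 5
fiber_span_mm: 50.0
post_window_ms: 1.5
depth: extradural_above_dura    # then: intradural_above_cord
```

run `cordstim recruit --config survey.yaml` for each depth. The two
printed summaries (abridged):

```
extradural_above_dura : r_access_ohm 1020.7   v50_v 40.25    power50_w 1.59      dc0_pct 80.0
intradural_above_cord : r_access_ohm  119.5   v50_v  0.242   power50_w 0.00049   dc0_pct 92.5
```

`R_a` is the Ohmic load the tissue presents to the stimulator; `V50`
the stimulus amplitude activating half of the DC fibers; `P50` the
average pulse power at that amplitude; `DC0` the fraction of DC fibers
recruitable before any dorsal-root fiber fires. Moving the lead inside
the dura cuts the access resistance by roughly an order of magnitude
and the power to reach the dorsal columns by far more than 90 %, while
selectivity improves — the central result this model family exists to
quantify.

The `cordstim` CLI also exposes `fixtures` (write the patient,
conductivity and electrode tables), `solve` (field solve only),
`evaluate` (adds the dermatome report), `compare-designs` and `verify`
(the analytic-oracle suite).

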