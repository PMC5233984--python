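# Methods

## Problem

High-definition transcranial direct current stimulation (HD-tDCS) loses
most of its injected current to scalp shunting and the poorly conducting
skull. A *transcranial channel* — a biocompatible conductive implant
(titanium here) traversing the full skull thickness, I-shaped (shaft
only) or T-shaped (shaft plus a hat disc) — has been proposed as a
skull/brain interface that conveys the current to the target without
breaching the dura. This package quantifies what such a channel does to
(i) the induced electric field in the cortex and (ii) the sub-threshold
membrane polarization of pyramidal neurons beneath the target, using a
two-stage computational model: a quasi-static volume-conduction solve
followed by passive compartmental cable solves driven by the computed
extracellular potentials.

## Synthetic head geometry

The head is a parametric labeled voxel model, not an MRI segmentation:
flat scalp (5 mm), skull (7 mm), dura (0.5 mm), CSF, gray matter (2.5 mm
band) and white matter stacked along z, with the CSF/GM interface carrying
one sinusoidal gyral ridge ("hand-knob-like" crown, amplitude 3 mm,
wavelength 20 mm) centered beneath the montage. CSF is 2 mm thick at the
crown. The default grid spacing is 0.5 mm (isotropic), chosen so the
smallest 1 mm channel shaft spans two cells; the lateral extent (84 mm)
accommodates the return ring with margin. All defaults are configurable
through one YAML document with unknown-key rejection.

The 4×1 montage is one active disc electrode (height 1 mm, radius 4 mm)
over a 2 mm gel pad on the scalp, and four identical return assemblies on
a 35 mm ring. Injected current is 1 mA. The channel is carved strictly
inside the skull layer (so it spans exactly the skull thickness and label
counts are conserved). The T hat (diameter = shaft + 1 mm, thickness
1 mm) sits at the outer (scalp-side) skull table by default, like the
head of an epidural screw: there it collects current over its wider
face and funnels it down the shaft, which is what makes the T shape
slightly stronger than the I shape; a hat placed against the dural
table instead spreads the current before it reaches the cortex and
weakens the T shape below the I shape. The hat side remains a config
option.

Conductivities (S/m, isotropic): scalp 0.465, skull 0.01, dura 0.065,
CSF 1.65, GM 0.276, WM 0.126, gel 0.30, electrode 5.8e7, titanium channel
7.4e5. Air is non-conducting and excluded from the system.

What the generator deliberately does **not** emulate: anatomical folding
beyond a single ridge, skull inhomogeneity, anisotropy, or the real
hand-knob Ω shape. Absolute field magnitudes and focality volumes
therefore differ from values obtained on MRI-derived anatomy; the tests
assert the *relations* the study design probes (channel vs none, shaft
diameter trends, T vs I, displacement decay, compartment-specific
polarization signs), which are robust to the simplification.

## Volume conduction

The potential obeys the quasi-static equation div(sigma grad phi) = 0
with 1 mA injected uniformly over the active electrode's exposed top
faces (Neumann), ground (phi = 0) on the return electrodes' top faces
(Dirichlet), and natural insulation elsewhere.

Discretization is node-centered finite volumes on the voxel grid: the
conductance of the edge between adjacent nodes is (h/4)·Σ sigma over the
(up to four) cells sharing the edge, h the spacing in meters. The scheme
is exactly locally conservative — the discrete current balance holds at
every free node — so the net flux through any closed node surface equals
the enclosed injected current up to solver tolerance. This property is
what makes the 1 mA conservation check an identity rather than an
approximation.

Metal bodies (electrodes, channel) are collapsed to equipotential
super-nodes before solving. Titanium exceeds tissue conductivity by more
than five orders of magnitude, so the sigma→infinity limit is exact to
about 1e-8 relative here, while keeping the explicit metal conductances
in the matrix would (a) make the 1e-9 relative-residual target
unattainable in double precision (the attainable residual scales with the
largest matrix entry) and (b) create near-kernel "floating plateau" modes
that defeat grid-based preconditioning. The merge threshold
(1e3 S/m) and the preconditioner conductivity cap are `SolverConfig`
fields; setting the threshold above the metal conductivities restores the
explicit formulation (used in the channel-conductivity monotonicity
test, which sweeps sigma from skull-like to titanium).

The reduced SPD system is solved by conjugate gradients to a relative
residual of 1e-9 (deterministic; no randomness anywhere in the solve),
preconditioned by a geometric multigrid V-cycle: coarse lattices on the
even nodes, Galerkin (P^T A P) coarse operators with trilinear transfers,
damped-Jacobi smoothing (omega = 0.8, 2 pre/post sweeps), and a direct
factorization on the coarsest level. Dirichlet and isolated-air nodes are
masked out of the transfers; their identity rows live on a voltage scale
and would otherwise leak into the current-scale coarse equations. On the
default head (~1.9M nodes) the solve takes 30-60 CG iterations.

Per-cell fields are E = −grad phi from the eight cell-corner potentials
(edge differences averaged per direction); potentials are sampled at
arbitrary points by trilinear interpolation.

## Field metrics

Cortical surface normals come from the gradient of a Gaussian-smoothed GM
indicator (sigma = 2 cells), orientation-checked against label adjacency
so they point from GM into CSF. The field on boundary cells splits into a
signed radial component — positive meaning directed *into* the cortex,
the depolarizing direction under anodal stimulation — and a tangential
magnitude |n̂ × E|; the split is norm-preserving.

Focality is Vol_p (p = 50, 60, 70, 80): total volume of GM cells whose
|E| strictly exceeds p% of the GM peak. The peak cell itself always
counts (p < 100), so a uniform field yields the full region volume; ties
at the peak resolve to the lowest linear cell index. "Cortex" means GM
only, not GM+WM. Relative focality is reported as Vol_50/Vol_80 (larger =
more diffuse).

## Neuron models

Two parametric pyramidal-cell stand-ins are generated deterministically
(SWC import provides the upgrade path to real reconstructions; files are
standard 7-column, with type code 5 used for the initial segment):

* **L5**: soma (20 µm), apical trunk with a small tuft, two basal
  dendrites, initial segment, and an axon that descends to the GM/WM
  boundary (landmark `b1`), bends (`b2`) and runs horizontally in the
  white matter to `terminal`. Probe landmarks: `d2` apical tip, `d1` tuft
  side branch, `d3` mid-trunk, `d4` basal tip.
* **L3**: shallower cell whose axon stays inside the GM (landmarks `mid`,
  `terminal`); dendrite probes `d1`, `d2` (apical tip), `d3` (basal tip).

Placement aligns the apical axis with the outward cortical normal, puts
the L5 soma at 0.75 of the local GM thickness and the L3 soma at 0.4
(layer depths are a design choice — the source does not state them
numerically), stretches the apical trunk so the tip reaches the layer-1
band (top 10% of GM), and stretches the L5 descending axon so `b1` lands
on the GM/WM boundary; scale factors are recorded per placement. The ROI
is a 5 mm-radius disc on the crown; a deterministic 0.84 mm square
lattice fills it with ~112 neurons (the reference population density).
The population is built once on the pristine head and reused across all
configurations of a sweep, since neither the channel (inside the skull)
nor the montage (above the scalp) moves the CSF/GM surface.

## Cable polarization

Sub-threshold steady-state polarization of a passive cable is linear, so
the transmembrane deviation v (mV, depolarization positive) solves
(G_ax + G_m) v = −G_ax e, where e holds the extracellular potentials at
compartment centers (sampled from the FEM solution, converted V → mV, or
synthesized as e = −E·x for a uniform field), G_ax couples parent/child
compartments through series half-compartment axial resistances
(4 R_a l / (pi d^2) per half; this reduces to the textbook
pi d^2/(4 R_a l) on uniform chains), and G_m is diagonal with
pi d l / R_m. Sealed ends are the natural boundary condition; the soma
root is a cylinder of length equal to its diameter (the equivalent-area
sphere). Compartments are auto-subdivided to l ≤ 0.1 lambda(d).

Membrane constants default to R_m = 30000 Ω·cm², R_a = 150 Ω·cm,
C_m = 0.75 µF/cm² (used only by the verification-mode backward-Euler
integrator, which reproduces the linear steady state after 10 time
constants). The source inherits its values from a reference we do not
hold, so these are declared, config-overridable stand-ins. A constant
extracellular offset produces exactly zero polarization — only potential
gradients matter.

The somatic coupling constant k (mm) is the somatic polarization (mV) per
unit local field (mV/mm = V/m, numerically identical), with the local
field interpolated at the soma; populations report mean ± SD.

### Morphology sensitivity

Two results guide the sensitivity analysis. First, enlarging the soma
monotonically reduces its polarization (larger local membrane area loads
the node). Second, the "flat dendritic tree" comparison: pure vertical
compression of a passive cell in a uniform field *reduces* somatic
polarization — polarization scales with the cell's extent along the
field while lambda is unchanged — so flatness alone cannot reproduce the
larger somatic response of the flat reference cells. Those cells are
also markedly thicker-trunked, and lambda grows like sqrt(d); the shipped
`type23_variant()` preset (flatness 0.6, trunk 10 µm, tuft 4 µm) is
flatter *and* more strongly depolarized than the default tall cell. The
pure-compression scaling law is pinned by its own test.

## Experiments

* **Channel dimension**: shapes {none, I, T} × shaft diameters
  {1, 3, 5, 7, 9} mm at zero displacement. Expected relations on this
  geometry: any channel raises the GM peak field and somatic
  polarization; the peak rises with diameter up to 7 mm and not at 9 mm;
  T ≥ I; the no-channel field is more diffuse (larger Vol_50/Vol_80).
* **Displacement**: T-shaped 7 mm channel fixed on the target, the whole
  five-electrode montage displaced rigidly along x (perpendicular to the
  gyral ridge) over {0, 5, 10, 15, 20} mm. Peak somatic polarization is
  non-increasing; retention is normalized to the aligned montage.

Each configuration runs build → carve → montage → solve → metrics →
polarize → aggregate; a failure aborts only that configuration. ROI
statistics use the linear-interpolation quantile convention (median, Q1,
Q3, min, max per landmark). Reports (`focality.csv`,
`polarization_stats.csv`, `retention.csv`, `run_manifest.json` with the
resolved config and grid-label hashes) are byte-reproducible for
identical configurations.

## Problem sizes and numerical tolerances

The default head at 0.5 mm spacing has ~1.8M grid cells; one conduction
solve converges in 30-60 preconditioned CG iterations to rtol 1e-9. The
sphere validation uses a 20 mm homogeneous sphere at 1 mm spacing and
matches the closed-form conducting-sphere solution to 1.4% relative L2
over the surface (electrode caps excluded, where the point-source
reference is singular); the discretization is second-order, so the error
falls with spacing. The cable validation uses a 201-compartment fiber
(0.5% end-polarization error vs the sealed-end closed form; midpoint zero
to rounding). The sparse compartmental solve agrees with a dense direct
solve to 1e-10 relative on random trees.

## Known limitations

* Absolute field magnitudes and focality volumes are geometry-bound;
  only relations are transferable to realistic anatomy.
* Passive membranes: no active conductances, thresholds, or synapses.
  The steady-state linearization is the standard model for sub-threshold
  polarization but cannot speak to firing.
* The equipotential-metal formulation makes results independent of the
  exact metal conductivity once it exceeds the merge threshold (the
  physical difference is ~1e-8 relative).
* Isotropic conductivities; no dura sensitivity analysis, heating, or
  electrochemical safety modelling.
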