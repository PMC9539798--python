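# Methods

`vheart` simulates one heartbeat of whole-heart electrophysiology on a
fully synthetic four-chamber anatomy and computes the 12-lead ECG, body
surface potential maps (BSPMs) and electrograms from it. This note
describes the models, the parameters that matter, the numerical choices,
and what the synthetic anatomy can and cannot stand in for.

## Synthetic anatomy

Subject-specific imaging is replaced by an idealized parametric anatomy,
meshed deterministically on a regular voxel lattice (Kuhn 6-tetrahedron
subdivision, conformal by construction; no RNG anywhere in the mesher):

* **LV** — truncated thick-walled ellipsoid, cavity semi-axes
  25 x 25 x 60 mm, wall 10 mm, base plane at z = 0.
* **RV** — crescent formed by an offset ellipsoidal shell (wall 4 mm)
  wrapped around the LV epicardium; it does not reach the apex.
* **Atria** — spherical shells (wall 2.5 mm) above an open AV plane.
  The only inter-atrial connections are a Bachmann's-bundle cylinder
  (fast-conducting) and a fossa-ovalis-rim bridge; atria and ventricles
  share no mesh nodes, so the intracellular space is electrically
  isolated at the base and the sole atrio-ventricular route is the
  1-D AV-node cable.
* **Torso** — elliptic cylinder 280 x 200 x 500 mm with two lung
  ellipsoids; the heart is embedded with a physiological long-axis tilt
  (apex left-anterior-inferior). Standard 12-lead electrode sites are
  snapped to torso-surface nodes; RL is the electrical ground.

Default mesh resolutions are 2.5 mm (heart) and 8 mm (torso),
preserving the fine-cardiac/coarse-torso ratio typical of ECG forward
models at desk scale. Heart geometry defaults are calibration targets:
with the default conduction system they yield a sinus QRS near 85 ms,
and the AV-node tuner can reach a PR of 200 ms.

Anatomical frame coordinates (apicobasal, transmural, rotational) are
computed from the parameterization itself rather than by Laplace
solves: the transmural coordinate is distance-based
(`t = d_endo / (d_endo + d_epi)` against the discrete endo-/epicardial
surfaces, so surface nodes sit exactly at t = 0 / t = 1), apicobasal and
rotational follow the ellipsoid axes. This is far cheaper than
harmonic coordinates and plays the same role (placing structures and
parameterizing fibers).

**Fibers.** Ventricular fibers follow the rule-based transmural
rotation, helix angle `alpha(t) = +60deg -> -60deg` linear in t,
applied in the circumferential-apicobasal tangent plane; the frame
(f, s, n) is orthonormal with n transmural. Atrial fibers are a
parametric surrogate for atlas mapping: circumferential per chamber,
axial along the Bachmann-bundle and FO-rim bridges.

## Conduction system

The His-Purkinje system is a stochastic fractal tree grown on the
endocardial surfaces (LV endocardium; RV septal surface, i.e. the LV
epicardial surface facing the RV cavity; RV free wall): cables of drawn
length ~ N(6 mm, 1 mm) truncated to [3, 9] mm, binary branching with
sibling repulsion >= 45 deg (jittered), collision avoidance radius 2 mm
with deflection retries up to +-120 deg, breadth-first concurrent
growth of all five fascicles (LV septal/anterior/posterior, RV septal,
RV moderator band — the moderator-band cable crosses the RV cavity to
the free wall and is the only fascicle allowed off the subendocardial
surface band). Growth terminates at surface boundaries, collisions and
a generation cap; terminal leaves become Purkinje-myocardial junctions
(PMJs) mapped to the nearest subendocardial node of the correct
chamber, with 8 ms antegrade / 3 ms retrograde transmission delays
applied per PMJ. Cables conduct at 2.0 m/s and are discretized to
500 um segments. The default network carries ~1400 PMJs on ~36k tree
nodes; the subject-scale network statistics of a patient model (e.g.
~1k PMJs at 1.2 mm mesh resolution on real anatomy) are not a target.

Fascicular timing is imposed by terminal-cable CV tuning: with every
cable at 2.0 m/s the His-rooted activation map gives each root's
untuned arrival; the last cable before the root is re-assigned
`cv = length / (desired delay - arrival at cable head)`, which makes
the root arrival exact (acyclic graph). Default delays
(16/22/24/18/24 ms after His for septal/anterior/posterior LV, septal
RV, moderator band) are surrogates chosen so the sinus QRS lands near
85 ms; personalized values would replace them when fitting a subject.

The AV node is a topologically simple 1-D cable (8 mm) joining a basal
right-atrial node to the His bundle; conduction is bidirectional, and
fast/slow AV-nodal pathways are not modelled. Its CV is tuned so that
the measured PR interval of the simulated sinus ECG hits the target
(200 ms): because the cable rigidly shifts every ventricular event by
`L/cv`, the tuner bisects on the exact shift identity anchored at one
measured PR and then verifies (and, if needed, corrects by secant steps
on further full simulations) until |PR - target| <= 1 ms. On the
default anatomy the tuned CV comes out at 0.065-0.077 m/s depending on
the growth seed.

## Activation

Myocardial activation solves the anisotropic Eikonal equation
`sqrt(grad T . M grad T) = 1` with squared-speed tensor
`M = vf^2 ff' + vs^2 ss' + vn^2 nn'`. Conduction velocities: ventricles
0.6 m/s longitudinal with 4:2:1 off-axis ratios (0.6/0.3/0.15); atria
1.2 m/s with 0.6 m/s off-axis; Bachmann's bundle 2.25 m/s with
0.8 m/s off-axis; the FO rim and SAN region conduct as atrial
myocardium. Units are mm/ms throughout, numerically equal to m/s.

The solver is an active-list fast-iterative method with an exact
closed-form local solver per tetrahedron face (vertex/edge/face
candidates of the constrained minimization), tolerance 1e-3 ms. It is
exact for lattice-aligned planar waves and first-order convergent for
tilted anisotropy; an edge-graph Dijkstra is kept as a test oracle only
(it overestimates off-lattice). Sinus rhythm starts at the SAN node
after a 25 ms electrical baseline.

Tree and myocardium are coupled bidirectionally by fixed-point
iteration: tree graph times given myocardial activation at PMJs (+3 ms
retrograde) and the AVN entry; then the myocardium re-solved with PMJ
arrivals (+8 ms antegrade) as point sources; iterated until no
activation time moves by more than 0.1 ms. Complete bundle-branch
block removes the proximal trunk edges of one side; the distal network
remains retrogradely excitable through its PMJs, which reproduces the
slow transseptal activation with late fast re-engagement seen in LBBB.

## Membrane and repolarization

Cellular dynamics are the two-variable Mitchell-Schaeffer model
(nu_gate 0.13, tau_close 175 ms, tau_in 0.3 ms, tau_out 5.4 ms;
tau_open is not constrained by the source parameterization and defaults
to 120 ms), with the dimensionless potential mapped between -86.2 mV
(rest) and 40 mV (peak). The stimulus convention is a 1 ms current
pulse whose amplitude (0.832 /ms) is calibrated once so a suprathreshold
beat from rest peaks at the prescribed 40 mV. Explicit Euler at
dt = 0.05 ms (guard: dt <= 0.2 tau_in).

Two APD measures are distinguished deliberately:

* the **plateau duration** (40%-repolarization crossing) tracks the
  analytic `APD_max = tau_close ln(tau_out / (4 tau_in))` — the time at
  which the plateau branch disappears in a saddle-node — to within 2%;
* **APD90**, which defines the repolarization time RT, additionally
  contains the slow post-saddle-node collapse and exceeds the analytic
  limit by 10-25% depending on tau_close. This is intrinsic model
  dynamics (the h-gate crosses `4 tau_in / tau_out` exactly at the
  analytic time), not an integration artifact.

Repolarization heterogeneity is prescribed by the linear
activation-recovery-interval map `ARI(x) = m AT(x) + b`
(m = -0.66, b = 215 ms) evaluated on the ventricular activation map
referenced to ventricular onset (the His-driven map); atria and the HPS
receive the maximal ventricular ARI. The map is converted to a spatial
tau_close field by numerically inverting the simulated APD90(tau_close)
relation, so that RT - AT reproduces the prescribed ARI by
construction (regression slope 1.00); the analytic inversion
`tau_close = ARI / ln(tau_out/(4 tau_in))` is available but, used
directly, would make RT - AT ~= 28 ms + 1.06 ARI. The sinus-derived
tau_close field is reused unchanged in every pathology.

Full-mesh transmembrane traces use the diffusionless reaction-Eikonal
reconstruction: each node plays a template action potential (one per
1 ms tau_close bin, linearly interpolated in time) shifted to its
activation time over a 700 ms beat at 1 ms sampling. Tree-internal
sources are not added to the ECG integral (Purkinje tissue volume is
negligible).

## Forward ECG

Lead fields are computed once per anatomy: for each electrode, unit
current is injected against the RL ground and
`div(sigma grad Z) = 0` solved by linear tetrahedral FEM on the torso
mesh (piecewise-constant conductivities: lungs 0.0389, blood 0.7,
general torso 0.22 S/m; myocardium sigma_i + sigma_e with sigma_i
fiber-aligned 0.174/0.019 S/m and sigma_e 0.22 S/m isotropic; sparse LU
factorized once). The ECG is the bilinear form
`phi_e(t) = -Z_e' K_i Vm(t)` with the sigma_i stiffness assembled on
the fine heart mesh; Z is carried between meshes by an explicit
trilinear lattice projector P. Scaling sigma_i rescales amplitudes
only. Standard 12-lead algebra (Einthoven by construction, Goldberger,
Wilson central terminal) produces the leads; simulated ECGs are
filtered zero-phase (3rd-order Butterworth, 150 Hz low-pass, 0.5 Hz
high-pass; optional 50 Hz notch for measured inputs).

Pseudo-bidomain recovery solves, at selected instants (default every
5 ms), `div((sigma_i+sigma_e) grad phi) = -div(sigma_i grad Vm)` on the
torso mesh with the RL-pinned gauge, the source Galerkin-projected from
the fine heart mesh through `P'`. Because both routes then share the
same discrete source functional, recovered electrode potentials match
the lead-field ECG to solver precision — the dual-formulation check is
exact rather than approximate. BSPMs are the recovered potentials on
the torso surface; electrograms are probes at arbitrary nodes.

The infinite-medium pseudo-ECG
`phi = 1/(4 pi sigma_b) int grad Vm . grad(1/r) dV` is a fast
cross-check. On the bounded, inhomogeneous torso it tracks the
lead-field ECG only where its assumption is defensible: left-lateral
electrodes (V5/V6, CC ~ 0.97-0.98 over the QRS); anterior electrodes
sit on the insulating boundary directly over the lungs and correlate
poorly (CC 0.2-0.6) — volume-conductor physics, not implementation
error, as the identical integral routed through the lead-field
machinery with analytic unbounded Z agrees with the direct integral to
CC = 1.000.

## Scenarios and ECG analysis

Scenarios combine rhythm (sinus/paced), block (none/left/right) and CV
condition (normal, or longitudinal CV reduced to 0.3 m/s in the
affected ventricle with off-axis ratios preserved). Lead fields, tree,
fascicular tuning, AVN tuning and the repolarization field are
computed once on sinus and reused; every run emits a manifest (full
configuration, seed, config hash, tree statistics).

Interval measurement uses the RMS envelope across the 12 leads with an
adaptive threshold (5% of the RMS peak, 10 ms debounce): the run
containing the envelope maximum is the QRS, its predecessor the P wave,
its successor the T wave; PR is P onset to QRS onset, QT runs to the
tangent-method T end. A broad blocked QRS merges with its discordant T
above threshold; runs longer than 250 ms are split at the deepest
post-peak envelope valley. Beat splitting/averaging detects QRS peaks
on lead I above 0.2 mV; comparison metrics are per-lead RMS difference
(L2, normalized by sample count) and Pearson correlation, averaged over
the 12 leads, after scaling the simulated signal by 0.32.

Bundle-branch-block criteria are operationalizations of the clinical
language, all thresholds configurable and logged in the report: QRS
> 120 ms; a notch is >= 2 same-sign local extrema with amplitude >= 5%
of the peak (1% prominence floor against numerical ripple); "W-shaped"
V1/V2 requires a dominant negative complex with >= 2 troughs; "notched
positive R" in V5/V6 tolerates opposite deflections up to 25% of R;
ST/T discordance compares the sign of the post-QRS area against the
dominant QRS area. For RBBB the V1/V2 criterion is a dominant positive
R complex — either monophasic R or the classic rsR' ("M") pattern; on
this synthetic anatomy the rsR' form manifests (the strict monophasic
variant, reported separately, is false here).

## Default problem sizes and runtime

Heart mesh ~25k nodes / 125k tets (2.5 mm); torso ~46k nodes / 250k
tets (8 mm); tree ~36k discretized nodes, ~1400 PMJs. One full
pipeline (anatomy, lead fields, growth, both tunings, sinus beat) runs
in about a minute on one CPU core; each additional pathology beat costs
a few seconds. These sizes are the package defaults and all are
configurable.

## What the synthetic data do and do not show

The generator emulates the geometry, tissue organization, conduction
system and torso inhomogeneity needed for qualitatively correct ECG
genesis: P-QRS-T ordering, physiological QRS/PR after calibration,
correct precordial progression and block morphologies. It does not
reproduce any real subject: no trabeculation, valves, pericardium,
bones or skeletal muscle; parametric rather than atlas atrial fibers;
idealized electrode geometry. Passing tests therefore demonstrate the
correctness and internal consistency of the methods at desk scale, not
agreement with a measured ECG; quantities that require the
(unavailable) subject recording and mesh — measured-vs-simulated
CC = 0.89 / L2 = 0.08, subject network statistics (958 PMJs, ~32k HPS
nodes), subject block QRS durations, and wall-clock performance claims
— are explicitly out of scope.

## Known limitations

* Voxel (staircase) surfaces; smooth-surface meshing would sharpen
  morphology details at equal node count.
* The diffusionless reaction-Eikonal omits electrotonic smoothing of
  the upstroke and repolarization gradients; ST segments are flat by
  construction of the Mitchell-Schaeffer plateau.
* The discrete Eikonal undershoots slightly at colliding-wavefront
  ridges (concave minimum under linear face interpolation).
* Atrial repolarization uses the maximal ventricular ARI, so the
  atrial T wave is schematic.
* Interval detection is envelope-based; noisy or low-amplitude signals
  may need threshold adjustments.
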