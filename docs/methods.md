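# Methods

## Scope and model

The package quantifies how flattening and in-plane expansion of a curved
transmembrane domain (TMD) converts membrane tension into channel opening.
The energetic model is deliberately minimal: a two-state (closed/open)
channel whose states differ in midplane bending angle (θ_c, θ_o), in-plane
radius (R_c, R_o) and footprint area (ΔA), embedded in a bilayer of bending
modulus K_b. The open-minus-closed free energy at tension σ is

    ΔG(σ) = ΔG₀ + π (θ_c² R_c − θ_o² R_o) √(σ K_b) − σ ΔA      [kBT]

and the midpoint tension σ½ solves ΔG = 0 with ΔG₀ = 0. Deliberately
excluded: hydrophobic-mismatch energetics (the TMD is assumed to keep a
constant hydrophobic thickness through the transition), continuum
"membrane footprint" mechanics, and any intrinsic conformational energy
ΔG₀ (it defaults to 0 and is an explicit argument wherever it enters).

A consequence worth knowing: because the bending term grows like √σ, ΔG(σ)
first *rises* from ΔG₀ before the −σΔA term dominates, so the model's
P_open(σ) is not monotone at very low tension and dips slightly below its
σ→0 limit. This is a property of the √σ approximation and is reported
as-is rather than smoothed away.

### Units and parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| θ_c, θ_o | closed/open midplane bending angle | rad (deg at API surfaces) | π/6, π/12 |
| R_c, ΔR | closed in-plane radius, radius change | nm | 7.813, 1.1 |
| ΔA | in-plane area change | nm² | 54 (= 2π R_c ΔR) |
| K_b | bilayer bending modulus | kBT | 20 |
| ΔG₀ | intrinsic conformational energy | kBT | 0 |
| σ | membrane tension | kBT/nm² (≈ 4.114 mN/m at 298 K) | — |

The canonical MscK defaults reproduce σ½ = 0.1587 → 0.16 kBT/nm². The
22 Å in-plane expansion is interpreted as a *diameter* change, so
ΔR = 1.1 nm and R_c = ΔA/(2π ΔR); this is the only reading that makes the
printed ΔA, ΔR and σ½ mutually consistent, and the root-found midpoint
(which uses the actual ΔA) agrees with the closed form (which assumes the
thin annulus) to 1e-8 relative under exactly that consistency.

`midpoint_tension_root` uses plain bracketing bisection to 1e-10 relative
tolerance — deterministic and dependency-free; the analytic root of the
balance equation is used only to seed the bracket.

## Geometry measurements

All measurements assume the canonical frame: symmetry axis on z, periplasm
at +z, structure centroid at z = 0. Frames are established by exhaustive
Cₙ scan (orders 2..max) with the trial axis taken from the best-fit plane
through chain centroids, refined by a Kabsch fit of the cyclic chain
permutation; ties between divisor orders break toward the higher order.
Azimuth is pinned by rotating the first subunit's centroid to azimuth 0,
which makes alignment idempotent and frame recovery after arbitrary rigid
motion exact to numerical precision.

* **Midplane bending angle.** Each chain's in-slab atoms are split into
  contiguous-residue runs (≥ 4 atoms), each run reduced to its centroid,
  and z regressed on radial distance r pooled over all runs;
  θ = arctan|dz/dr|. For a cone-shaped midplane this recovers the cone
  deflection exactly regardless of the pivot radius. The slab should cover
  the full TMD; runs shorter than 4 atoms (e.g. single pore-ring residues)
  are ignored.
* **In-plane radius/area.** Area of the 2D convex hull
  (scipy.spatial.ConvexHull) of the in-slab atoms projected on xy;
  R = √(A/π). The default band is the whole slab — the footprint that the
  tension term σΔA acts on — not a thin midplane slice.
* **Height.** The 2.5–97.5 percentile z-span rescaled by 100/95. The raw
  percentile span of a uniform axial density underestimates the true span
  by exactly 5%, so the rescaling makes the estimator exact for uniform
  density while staying robust to a small fraction of stray atoms.
* **Ring diameter.** Twice the maximum radial atom distance of a residue
  selection (outer diameter). Whether side chains are included is up to
  the selection; the synthetic ring presets are single-atom-per-residue so
  the question does not arise there.
* **State deltas.** Closed/open profiles can only be differenced when
  measured under the same *slab convention* (a label such as "explicit" or
  "tm-extent"); the numeric bounds may differ between states because the
  membrane boundaries of a curved and a flattened conformation genuinely
  do. ΔA is by definition A_open − A_closed; a flag records whether it is
  also annulus-consistent (|ΔA − 2πR_cΔR|/ΔA ≤ 0.15), which is what the
  closed-form σ½ assumes.

## Pore profiling

At each axial position the pore radius is the largest sphere radius
r(z) = max over probe centers c (within a bounded "wander" of the axis) of
min over atoms (|c − atom| − r_vdW), clamped at 0. The maximization is a
deterministic grid search (default step 0.5 Å, center resolution step/2,
wander 5 Å) rather than the simulated annealing of classic profilers: it
is reproducible bit-for-bit and directly checkable against a brute-force
dense-grid oracle, which the tests do on ≤ 500-atom instances (agreement
within step/2 guaranteed by construction). Radii are Bondi van der Waals
values (C 1.70, N 1.55, O 1.52, S 1.80 Å), hydrogens excluded, side chains
included by default. Gates are local minima of the moving-average-smoothed
profile with radial prominence ≥ 0.5 Å (boundary minima count, so a
monotone funnel reports its narrow end); lining residues are those with an
atom within 1 Å of touching the probe sphere. Diameters are 2× probe
radius with no solvent offset.

## Electrophysiology

Traces are zero-phase lowpass filtered (4-pole Bessel-equivalent, 500 Hz
default, matching typical acquisition). The unitary conductance comes from
amplitude-density modes (fine histogram + Gaussian kernel smoothing with a
bandwidth set by a robust noise estimate; mode positions refined by
iterated local centroid, which makes the estimate invariant under baseline
offset and voltage sign to well under a picosiemens): the baseline is the
dominant mode (ties toward the level nearest zero), the open level the
*nearest* separated mode — the first conductance step — so stacked
multi-channel levels cannot inflate the estimate. g = |open − baseline|/|V|.
The standard error comes from per-event amplitudes of
half-amplitude-idealized openings, using interior samples only (within one
filter settle time of a transition the filtered trace has not reached the
open level).

First-activation pressures require a monotone suction ramp; openings are
detected as filtered-current steps (two-sided moving difference with a
settle window matched to the filter), classified by step amplitude into
per-channel-type bands (conductance × voltage ± 30%), and the first event
in the requested band reports its pressure magnitude. The sensitivity
ratio is calibrator/test first-activation pressure (e.g. P_MscL/P_MscK);
the endogenous MscL calibrator opens at a high reproducible tension, so a
larger ratio means a more tension-sensitive test channel. Conversion of
pipette pressure to absolute membrane tension is out of scope (it needs
patch geometry), as are dwell-time kinetics.

## Synthetic data

The structure generator builds Cₙ pseudo-atom bundles with analytic ground
truth, trading realism for exactness:

* Per subunit, vertical helical "tubes" (2.3 Å spiral radius, 1.5 Å rise,
  uniform carbon atoms) at evenly spaced radii; the midpoint of the helix
  at radius r sits at z = −tan(θ)(r − r̄), so the generated midplane is an
  exact cone of the requested bending angle.
* Pore constrictions are rings of one atom per subunit at distance
  (radius + r_atom) from the axis: a centered probe of exactly the
  requested radius touches them, so constriction diameters are exact by
  placement. Ring residues carry MscK-style labels (W914, V921, F925) so
  gate attribution is exercisable.
* A polar (serine) periplasmic cap at a configurable radius provides the
  orientation marker, the ring-diameter target and a polar/apolar contrast
  for the hydrophobic-belt slab heuristic.
* Seeded Gaussian jitter is applied last; every artifact carries its
  ground truth (true cone angle, true hull radius/area from the exact
  pre-jitter atoms, true constriction diameters, TM slab, seed).

The default closed/open pair mimics the MscK transition: 30° → 15°
bending, footprint radius 7.82 → 8.92 nm (the generator helix radii are
set so the *hull* radii land on the canonical R_c and R_c + 1.1 nm; the
7-fold azimuthal sampling shrinks a hull slightly below the nominal helix
radius), constrictions 2.5 Å (V921/F925) and 4 Å (W914) versus one 10 Å
open pore, periplasmic ring 154 → 178 Å, jitter 0.25 Å. The emergent
height reduction is ≈ 19 Å. What the mimic does *not* emulate: real
side-chain geometry, the kinked pore-lining helix, inter-subunit packing,
solvent, or partial disorder — so recovery tests validate the estimators'
correctness on idealized geometry, not their robustness to real cryo-EM
model pathologies.

The recording simulator drives channel populations with a linear suction
ramp (default 4 mmHg/s) or a pressure hold; gating is either a sharp
threshold or a two-state Markov "flicker" whose equilibrium open
probability is a Boltzmann function of pressure, evaluated quasi-statically
on a 1 ms tick grid. Unitary currents are g·V with seeded Gaussian noise
(default 2 pA at 5 kHz sampling); populations whose amplitudes are closer
than 3 noise SDs are flagged as overlapping. All randomness flows through
one seeded generator recorded in the ground truth.

## Verification sizes and determinism

The self-checks run at desk scale: 1000 random parameter sets for the
closed-form/root identity, ≤ 500-atom clouds for the pore oracle, a
5-point cone-angle grid with 0.3 Å jitter for geometry recovery, and 100
seeded 30-s patches (5 kHz) for conductance recovery — sizes chosen so the
whole suite runs in seconds while keeping every estimate's sampling error
far below its acceptance band. Identical configuration + seed reproduces
every number bit-for-bit.

## Known limitations

* The bending-angle definition (linear fit of segment-centroid z against
  r) collapses the full midplane shape to one number; strongly non-conical
  midplanes are summarized, not resolved.
* The hydrophobic-belt slab heuristic needs a genuine polar/apolar
  contrast; detergent-solubilized or heavily engineered constructs may
  defeat it (explicit bounds are always available and are the default).
* The pore profiler's bounded wander follows the classic straight-axis
  assumption; strongly curved permeation pathways are out of scope.
* Measurements on deposited coordinate files depend on conventions the
  structures themselves do not fix (membrane bounds, atom subsets);
  those choices are exposed as parameters rather than hard-coded.
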