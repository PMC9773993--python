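# Methods

## Physical model

Stimulation currents are DC, so capacitive and inductive effects are
negligible and the potential satisfies the quasi-static continuity
equation ∇·(σ∇φ) = 0 in the conductive volume, with zero normal current
on the body surface and on the truncation planes of the trunk. Each
electrode's metallic connector is an isopotential surface; the pair
injects a prescribed total current I. We solve the equivalent two-terminal
problem with connector potentials fixed at ±0.5 V and rescale φ, E = −∇φ
and J = σE by I_target/I_computed — for a linear two-terminal network this
is exactly the prescribed-current, isopotential-connector formulation,
without a constrained solve.

## Synthetic anatomy

The trunk is generated procedurally from geometric primitives rather than
segmented images. The aim is topological fidelity: the features that
dominate spinal current flow are the high-conductivity CSF channel, the
low-conductivity bone surrounding it, the intervertebral gaps where roots
and ganglia leave the canal, and the skin/fat/muscle layering under the
electrodes. Surface realism (organ shapes, curvatures) is deliberately
sacrificed.

Default geometry (all configurable via `AnatomyParams`, lengths in mm):
elliptical trunk 260 × 190 across, 460 tall, with 4 skin and 8 fat;
vertebral bodies r = 16, height 22, disks 6, for T5–L5 plus a sacrum
block; a lamina ring (thickness 5) around a canal of radius 10 at 35 mm
dorsal of center, with spinous processes reaching 30 further dorsally;
dura 2 thick; cord ellipse 11 × 8 with a 5 × 3.6 gray-matter core, conus
at the L1/L2 disk, cauda equina bundle (r = 3) below; root channels
(r = 2.5) through each T12–L5 foramen ending in DRG ellipsoids
(7 × 5 × 5) centered 15 mm lateral of the canal axis. Lungs, heart and
viscera are single convex blobs with their literature conductivities.

Coordinate convention: +x subject-left, +y dorsal, +z rostral; voxels are
cell-centered at `origin + (index + ½)·h`. Everything is stamped
mirror-symmetrically about x = 0 (including the heart, which is medially
centered here) so that midline montages produce exactly symmetric fields —
a property the left/right DRG tests rely on. Optional Gaussian jitter of
the spinous processes (`jitter_mm`, default 0, seeded) breaks the symmetry
on demand.

The cord ends are truncated with the model; the canal overshoots the
column top and both canal ends are capped with dura so the CSF
compartment stays strictly inside the dural sac. The skin shell is closed
over the trunk's top and bottom faces; since background voxels are
insulating either way, this does not change the current paths but keeps
the "closed outer shell" invariant checkable by ray casting.

Spinal segments T6–Co are mapped onto the cord extent (conus to canal
top) by relative length weights (thoracic 1.5, lumbar 1.0, sacral 0.35,
coccygeal 0.3), which places the lumbar segments adjacent to the T11–L1
vertebral bodies — the standard rostral shift of cord segments relative
to same-named vertebrae. The map is a configurable table, not an
anatomical claim. A z exactly on a boundary belongs to the more caudal
segment.

## Conductivities

Isotropic values (S/m): skin 0.435, fat 0.040, muscle 0.355, lungs 0.046,
heart 0.535, viscera 0.123, vertebrae/bone 0.006, disks 0.200, dura
0.030, CSF 1.790, roots 0.154, spinal WM 0.143, spinal GM 0.333; gel 4,
conductive rubber 44. Muscle and spinal WM are anisotropic with
longitudinal:transverse ratios r = 5 and r = 10 (common fibrous-tissue
values; the literature rarely states them for DC models, so both are
configurable and r = 1 recovers the isotropic model bitwise). Tensors
follow the volume constraint σ_long = σ_iso·r^(2/3),
σ_trans = σ_iso·r^(−1/3), so det σ = σ_iso³ exactly — the geometric mean
of the eigenvalues is the isotropic reference. WM fibers follow the local
cord tangent; paravertebral muscle fibers are taken as longitudinal
(body axis). The connector metal is represented as 1e6 S/m, which only
enters the contact-face conductance (the connector voxels themselves are
Dirichlet-eliminated).

## Electrodes

Each electrode is a 50 × 50 × 2.5 mm gel layer, a 49 × 49 × 1 mm rubber
pad and a 10 mm diameter × 1 mm connector disc embedded in the pad's top
face. The gel conforms to the curved skin: each footprint column is
filled from the local skin surface up to the flat pad base, so there is
no air gap (full gel–skin contact, as assumed by FEM models). Anchors are
vertebral landmarks — the T8 spinous process for the rostral electrode
and the L1–L2 interspinous point for the lumbar one — with a signed
lateral offset (+25 mm = left paravertebral). The lumbar electrode is the
cathode in all presets (cathodal-tsDCS convention); `reverse_polarity`
flips the Dirichlet signs without moving electrodes.

## Discretization and solver

Cell-centered finite volume on the uniform voxel grid. Face fluxes use
harmonic averaging of the face-normal tensor component (7-point stencil),
which reproduces 1-D layered solutions exactly when interfaces lie on
faces and yields an exactly conservative, symmetric M-matrix. Off-diagonal
tensor components add the symmetric 4-point cross stencil on edge-diagonal
neighbors (27-point); every pairwise coupling uses the arithmetic mean of
the two cells' σ_ab, keeping the matrix symmetric by construction, and
the diagonal is the negated off-diagonal row sum, keeping row sums zero
(exact discrete conservation). The cross terms can break the M-matrix
property, so the discrete maximum principle is only asserted strictly for
the 7-point case; on the default anatomy the straight cord and
body-axis muscle fibers make all tensors diagonal and the 7-point path is
used throughout. The 27-point path is verified by stencil-consistency
tests (interior rows annihilate linear potentials for uniform full
tensors) and by a brute-force assembly oracle on a tiny grid.

Connector voxels are eliminated as Dirichlet unknowns; conductive islands
with no path to an electrode are pruned with a warning (they would make
the reduced system singular). The reduced SPD system (~2.2 M unknowns at
2 mm) is solved with Jacobi-preconditioned conjugate gradients, zero
initial guess and fixed ordering (deterministic), to a relative residual
of 1e-10 — tight enough that the interior net-flux residual stays below
1e-6 of the injected current, the package's conservation budget; typical
cost is 1 200–1 400 iterations, about a minute on one CPU. Non-convergence
raises with the achieved residual.

E is obtained from φ by central differences where both neighbors share
the voxel's tissue label, one-sided differences into the same tissue at
label interfaces (preserving the |E| jump across conductivity contrasts),
and whatever conductive neighbors exist at domain boundaries. The
anode/cathode currents are discrete face-flux sums over the connector
surfaces; they agree to ~1e-9 relative on converged runs and a mismatch
beyond 1 % raises, as it signals a discretization bug.

## Analyses

E is projected onto the cord frame: E_long is the component along the
*caudal* direction (positive = rostral→caudal, the physiological sign
convention for a lumbar cathode), E_vd positive dorsal→ventral, E_rl
positive right→left. Slice statistics average E_norm as the mean voxel
magnitude and the components as signed means (so opposing directions
cancel); absolute values are taken only at the per-segment maximum step.
Slices default to 1 mm but never less than one voxel — at the 2 mm
default grid the analysis uses 2 mm slices. Empty bins are reported with
zero counts and NaN means, never zero-filled. The supra-threshold mask
uses E_norm ≥ 0.15 V/m, inclusive at equality (the conservative reading
of "exceeds"). DRG probes are spheres (default radius 2 mm) at the
ganglion landmarks; the direction read-out is the projection of the mean
probe field on the root axis, positive cord→periphery. "Segments between
the electrodes" are those whose z-range lies strictly between the facing
gel edges; segments under a footprint see strong transverse components
and are excluded from the longitudinal-dominance statement by
construction. Montage comparison averages E_norm over a stated DRG or
segment target, refuses runs with different anatomy digests (hashed on
the electrode-free grid) or currents, and breaks ties lexicographically.

## Verification

No reference field exists for the synthetic trunk, so the solver is
verified against closed forms: a homogeneous bar (linear φ, E = ΔV/L,
Ohm's-law current), a layered slab (piecewise-linear φ, continuous J_z, E
jumping by the conductivity ratio), and an anisotropic bar (Ohm's law
with σ_long). All agree within far less than 1 % at 1 mm. A slab with the
interface off the face lattice provides genuine discretization error; the
observed convergence order of the max-φ error over 4/2/1 mm is ≈ 1.7.
Current conservation is checked as the maximum interior net-flux residual
relative to I (≤ 1e-6 required, ~1e-12 typical).

## What the synthetic model does and does not show

Passing tests demonstrate that the *method* — assembly, solve,
conservation, decomposition, statistics — is correct, and that the
*qualitative* physics of tsDCS reproduces: field maxima in the lumbar
cord above the 0.15 V/m threshold at 4 mA, a dominant (≥ 85 %)
rostral→caudal longitudinal component between the electrodes, no
left/right DRG asymmetry for midline montages, and cathode-ipsilateral
DRG lateralization (~17 % here) with cord→periphery field direction on
the cathode side for paravertebral montages. Absolute magnitudes are
anatomy-dependent: detailed human models yield lumbar maxima around
0.6 V/m at 4 mA, while this smooth-canal trunk yields ~0.2 V/m — the same
order, but not comparable beyond that. Real anatomies also produce local
hotspots (CSF narrowings, root-exit funneling) that smooth primitives
cannot, so per-segment tables from this model should be read as method
demonstrations, not dosimetry for any subject.

## Known limitations

Voxel staircasing (no conforming mesh); no electrode–skin contact
impedance; no capacitive effects or ramp waveforms; straight cord (the
frame machinery supports curved centerlines, but the default generator
does not bend it); DRGs are few voxels at 2 mm, so probe values are
discretization-sensitive; the 27-point scheme loses the strict maximum
principle; conductivity uncertainty (notably bone and the anisotropy
ratios) is passed through, not propagated.
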