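# Methods

## The rotation measurement

The quantity of interest is a single scalar per trajectory frame: how far
the C-domain of a two-domain protein has rotated relative to the N-domain,
measured against an inactive/active pair of reference structures. The
measurement has three parts.

**Superposition.** All alignments are least-squares rigid superpositions of
matched Cα point sets (Kabsch). The implementation delegates the rotation
solve to `scipy.spatial.transform.Rotation.align_vectors` and adds the
translation, residual-RMSD and degeneracy handling around it: fewer than 3
points or a collinear point set raises, because the optimal rotation is not
unique there. Reflections are excluded (proper rotations only), all atoms
are weighted equally, and the residual is recomputed directly from the
superposed coordinates because the solver's internal residual loses
precision near zero. Atom correspondence between two structures is by
(chain, residue number, insertion code, atom name); mismatches raise with
the unmatched residues listed, rather than silently aligning different
atoms.

**Reference axis.** The active structure is superposed onto the inactive
one using the N-domain selection; the rotation-only Kabsch solution mapping
the centroid-removed inactive C-domain onto the aligned active C-domain
gives a rotation whose axis–angle pair (u, θ_ref) defines the activation
rotation. Pairs with θ_ref < 0.5° are rejected: the axis direction is
numerically undefined as θ → 0, and such a pair cannot anchor a signed
angle. θ_ref ≈ 20° for the arrestin-type activation this was designed
around.

**Per-frame twist.** Each frame is superposed onto the *inactive*
reference on the N-domain (the active structure enters only through u and
θ_ref). The rotation R_t from the inactive C-domain to the frame's
C-domain is decomposed swing–twist about u, and the signed twist

    θ_t = 2·atan2(v·u, w),  (w, v) the unit quaternion of R_t with w ≥ 0,

is reported, wrapped to (−180°, 180°]. This realization was chosen over
alternatives (projected dihedrals, full rotation angle) because it is
continuous, signed, exactly 0 at the inactive reference and exactly θ_ref
at the active one, invariant under rigid motion of the frame, and is the
standard decomposition for rotation about a prescribed axis. Anchoring the
alignment to the inactive structure alone keeps the scalar well defined;
aligning to both references and averaging would define a different (and
unsigned) quantity. Whether a signed or absolute angle better matches
historical analyses of this type is not determinable from published
descriptions; the signed convention is documented behavior, and
classification uses the signed value (negative angles are inactive-like).

## Population analysis

A frame is inactive-like iff θ_t < threshold, strictly; the default
threshold is 15°, and boundary frames are active-like. Fractions are pooled
over replicate runs with every frame weighted equally (identical to
run-averaging when runs have equal length, the usual replicate design).
Complementarity (inactive + active = 1) is enforced structurally.

Uncertainty comes from a circular block bootstrap within each run
(default block length 100 frames, 95% percentile interval): MD frames are
strongly autocorrelated, so an iid bootstrap would understate the
uncertainty severely. The block length should be at least the angle
autocorrelation time; for the synthetic two-state process with switching
probabilities ~0.02–0.03 per frame the correlation time is ~20–40 frames,
so 100 is conservative. The interval is deterministic given its seed.

## Contact analysis

Contacts are heavy-atom, distance-only criteria chosen from common
structural-biology practice, because published network figures of this kind
rarely state their exact cutoff: salt bridge ≤ 4.0 Å between a cationic
side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2 including the
tautomer residue names HSD/HSE/HSP/HID/HIE/HIP) and an anionic oxygen
(Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT, and SEP/TPO/PTR phosphate
oxygens in both the O1P/O2P/O3P and OP1/OP2/OP3 naming dialects);
hydrogen bond ≤ 3.5 Å between any two N/O atoms; weaker polar contact
≤ 3.9 Å. One record per atom pair with precedence salt bridge > H-bond >
polar. There is no donor/acceptor angle term — the crystal structures in
scope lack hydrogens — and only direct contacts are counted
(water-mediated bridging is out of scope; a crystallographic water can
appear only as a direct polar partner). Same-residue pairs are excluded by
default, sequence-adjacent pairs are kept (backbone i/i+1 H-bonds are
real); both exclusions are flags. Unknown residues degrade gracefully to
polar-by-element with a warning. Candidate pairs come from a KD-tree at the
largest cutoff; tests hold the result to exact equality with a naive
all-pairs double loop.

Network comparison between two conformations is set algebra on
(residue pair, kind) keys — atom-level records and distances are reported
per side, but a contact that merely switches which phosphate oxygen it uses
is the same edge.

## The synthetic generator

The generator produces the ground truth every stage is tested against; it
emulates the *geometry* of the measurement problem, not the physics.

Each domain is a pseudo-Cα chain wound ball-of-yarn style around a sphere:
consecutive chords are exactly 3.8 Å (the canonical Cα–Cα virtual bond),
and the sphere radius follows the empirical size of globular domains,
R = max(2.2·n^0.38, 1.21·√n) Å — the first term is the observed radius of
gyration scaling for folded domains, the second keeps successive windings
from packing closer than non-bonded Cα pairs ever do. The shell winding
gives a nearly isotropic inertia tensor (smallest/largest principal moment
≈ 0.65–0.9, far above the 5% conditioning floor), which matters because the
angular precision of the measurement is set by the domain's lever arm about
the (arbitrarily oriented) twist axis. The two domains sit on tangent
spheres joined by a single 3.8 Å chain step, so centroids are > 10 Å apart
for all supported sizes (n ≥ 10 per domain). A seeded random rigid motion
of the whole structure removes any preferred construction orientation.

The active reference is the inactive structure with its C-domain rotated by
θ_ref (default 20°) about the configured axis through the C-domain
centroid. Trajectory frames twist the C-domain by θ_t from either an
explicit schedule or a two-state Markov chain: inactive/active basins with
Gaussian jitter (means 5°/20°, SD 3° by default — separated by the 15°
threshold but with deliberate boundary traffic), per-frame switching
probabilities p_IA, p_AI, started from the stationary law. The jitter is
iid per frame rather than an Ornstein–Uhlenbeck process so the stationary
classified fraction has a closed form to test against: the hidden-state
occupancy is p_IA/(p_IA+p_AI) exactly, and basin overlap shifts the
classified fraction by a computable amount (with the defaults,
P(N(20,3) < 15) ≈ 4.8% of active frames classify inactive-like, so the
expected classified active fraction at p_active = 0.40 is ≈ 0.381).
Optional iid isotropic Gaussian coordinate noise (σ per coordinate
component) stands in for thermal fluctuation, and an optional independent
random rigid transform per frame stands in for diffusion of the molecule in
the box.

Randomness derives from one root seed via named substreams in a fixed
order (structure, states, jitter, noise, global motions), so regenerating
part of a system is stable and identical seeds give bitwise-identical
trajectories and files.

What the generator does *not* emulate: side chains, secondary structure,
force-field energetics, solvent, correlated internal motion within a
domain, or binder molecules — a conformational clamp (Fab-like) is
represented purely by shifting p_AI/p_IA. Passing tests therefore
demonstrate correctness of the measurement pipeline on rigid-domain
geometry with uncorrelated noise, not robustness to internal domain
plasticity; on real trajectories the angle additionally reflects genuine
domain deformation, which this package reports as-is through the alignment
RMSD column.

## File handling and numerics

PDB I/O is fixed-column and deliberately strict: one frame per MODEL block
(a file without MODEL records is one frame), HETATM phosphoresidues
retained, author residue numbering kept verbatim, alternate locations
collapsed by highest occupancy (ties alphabetical; a `first` policy is
available), malformed coordinate fields reported with their line number,
and MODEL blocks that disagree on their atom table rejected. Single-frame
files are written without MODEL/ENDMDL (crystal convention), multi-frame
always with; coordinates beyond ±9999.999 Å are refused rather than
silently corrupted. Round trips preserve coordinates to the 0.001 Å column
quantum. Hydrogens are read but excluded from contact chemistry; Cα
selections exclude them implicitly.

Rolling averages of angle series use a centered window (odd length
required) whose half-width shrinks symmetrically at the edges, so the
output has the input's length and no phase shift; the default window of 51
frames smooths ~1% of a typical deposited run and is a flag, not a
constant.

Problem sizes used by the test suite and the acceptance script — 100
random clouds × 1000 candidate rotations for superposition optimality, 20
seeds × 100 frames at σ = 0.2 Å for the noisy-recovery rate, 5 runs ×
4000 frames for population recovery (with the Monte-Carlo SE calibrated
over 200 replicates of the angle process), 50 random structures of 100–500
atoms for contact equivalence — were chosen as the smallest designs that
make the statistical checks sharp: each stochastic assertion sits several
standard errors from its pass boundary under the stated conditions.

## Known limitations

- The angle is defined only relative to a reference pair; comparing series
  built from different reference pairs (different axes) is not meaningful.
- No automatic domain decomposition: the N-/C-domain selections are user
  input, and on real structures the choice of β-strand ranges shifts the
  absolute angle by a few degrees, which matters near a classification
  threshold.
- Contact detection is distance-only; at boundary distances it will count
  geometrically unfavourable pairs that an angle-aware criterion would
  reject.
- Trajectories must be multi-model PDB; binary formats (DCD/XTC) need
  external conversion first.
- The block bootstrap treats runs as exchangeable replicates; systematic
  differences between runs (different starting basins, unconverged
  sampling) widen the interval but are not modelled.
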