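# domaintwist

Inter-domain rotation (twist) analysis for two-domain proteins, written for
the kind of question that comes up with β-arrestin-1: given an inactive and
an active crystal structure and an MD ensemble, how far has the C-domain
rotated relative to the N-domain in each frame, what fraction of the
ensemble is inactive-like versus active-like, and which residue-level polar
interactions (salt bridges, hydrogen bonds) distinguish the conformations?

It is a library first — the importable API plus the narrative scripts in
`examples/` are the main interface — with a thin `domaintwist` CLI for
shell-driven runs.

## The measurement

Let the inactive and active reference structures share matched Cα
selections for the N- and C-domain (typically the β-strand residues). The
reference rotation is derived once:

1. superpose the active structure onto the inactive one using the N-domain
   Cα atoms (Kabsch least-squares, reflections excluded);
2. the rotation-only Kabsch solution mapping the inactive C-domain onto the
   aligned active C-domain has axis **u** and angle θ_ref (≈20° for
   β-arrestin-1).

Each trajectory frame is then superposed onto the **inactive** reference on
the N-domain, the rotation *R_t* carrying the inactive C-domain onto the
frame's C-domain is computed the same way, and the reported angle is the
signed **twist** of *R_t* about **u** from the swing–twist decomposition:
for the unit quaternion (w, **v**) of *R_t* with w ≥ 0,

```
θ_t = 2 · atan2(v · u, w)   ∈ (−180°, 180°]
```

By construction the inactive reference scores exactly 0°, the active
reference exactly θ_ref, the value is invariant under any rigid motion of
the frame, and negative values (rotation past the inactive pose) are
meaningful. Frames with θ_t < 15° (strict) are classified inactive-like,
the rest active-like; fractions are pooled frame-weighted across replicate
runs, with a circular block bootstrap for uncertainty because MD frames are
autocorrelated.

Contact analysis is heavy-atom and distance-based (no hydrogens needed):
cationic side-chain N (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2) to anionic O
(Asp/Glu carboxylates, C-terminal OXT, SEP/TPO/PTR phosphate oxygens)
within 4.0 Å is a salt bridge; N/O pairs within 3.5 Å are hydrogen bonds,
within 3.9 Å weaker polar contacts; one kind per atom pair with precedence
salt bridge > H-bond > polar. All cutoffs are configurable.

Because the original β-strand selections and deposited trajectories are
external inputs, the package ships a fully ground-truthed synthetic
generator: two ball-of-yarn pseudo-Cα domains (exact 3.8 Å chain spacing,
empirical globular-domain radius 2.2 N^0.38 Å) whose C-domain twists about a
known axis, driven by either an explicit angle schedule or a two-state
Markov process with closed-form stationary occupancy, plus coordinate noise
and per-frame rigid tumbling. Every stage of the pipeline is verified
against this ground truth.

## Worked example

`python examples/01_twist_angle_recovery.py` builds a synthetic reference
pair, simulates a 9-frame trajectory with a known twist schedule and random
rigid tumbling, and recovers the angles:

```
reference rotation: 20.0000 deg about axis [-0.  0.  1.]

frame  applied(deg)  recovered(deg)  align-RMSD(A)
    0        0.0000    0.0000000000       1.24e-14
    1        2.5000    2.5000000000       7.27e-15
    2        5.0000    5.0000000000       1.34e-14
    ...
```

The applied twist is recovered to machine precision per frame; the
alignment RMSD column confirms the N-domain superposition is exact in the
noise-free case.

`python examples/02_conformational_populations.py` runs five replicate
Markov trajectories (p_IA = 0.02, p_AI = 0.03, stationary active fraction
0.40) through the full pipeline and classifies at 15°:

```
{
  "system": "synthetic two-state",
  "threshold_deg": 15.0,
  "n_runs": 5,
  "n_frames": 10000,
  "fraction_inactive_like": 0.6137,
  "fraction_active_like": 0.3863,
  ...
}
```

The classified active-like share (0.386) sits just below the hidden-state
stationary value (0.400) because the 20°-mean active basin leaks ~5% of its
frames below the threshold — exactly the behavior expected from the basin
overlap, and covered by the reported bootstrap CI.

`examples/03_contact_networks.py` shows phosphate-anchored salt-bridge
networks and their difference between two conformations;
`examples/04_cli_workflow.sh` is the same pipeline driven entirely through
the CLI (`simulate`, `angle`, `populations`, `contacts`,
`compare-contacts`).

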