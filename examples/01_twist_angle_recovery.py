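"""Measure an inter-domain twist-angle series on a ground-truthed trajectory.

Builds a synthetic two-domain protein, derives the rotation reference from
its inactive/active pair (the analogue of the 1G4R/4JQI beta-arrestin-1
crystal pair), simulates a short trajectory with a known twist schedule
plus rigid-body tumbling, and recovers the angles frame by frame.
"""

import numpy as np

from domaintwist import (
    SyntheticConfig,
    build_reference,
    build_two_domain_structure,
    domain_selections,
    make_reference_pair,
    rolling_average,
    simulate_trajectory,
    trajectory_angles,
)

config = SyntheticConfig(
    n_atoms_N=50, n_atoms_C=50, theta_ref_deg=20.0, seed=1, global_motion=True
)
structure = build_two_domain_structure(config)
inactive, active = make_reference_pair(structure, config)
n_sel, c_sel = domain_selections(config)

reference = build_reference(inactive, active, n_sel, c_sel)
print(f"reference rotation: {reference.theta_ref_deg:.4f} deg about axis {reference.axis.round(3)}")

schedule = [0.0, 2.5, 5.0, 10.0, 15.0, 17.5, 20.0, 15.0, 5.0]
ensemble, truth = simulate_trajectory((inactive, active), config, schedule=schedule)
series = trajectory_angles(ensemble, reference)

print("\nframe  applied(deg)  recovered(deg)  align-RMSD(A)")
for i, (applied, got, rmsd) in enumerate(
    zip(truth.theta_deg, series.angle_deg, series.alignment_rmsd_A)
):
    print(f"{i:5d}  {applied:12.4f}  {got:14.10f}  {rmsd:13.2e}")

smoothed = rolling_average(series, window=3)
print(f"\nrolling mean (window 3) of recovered angles: {np.round(smoothed, 3)}")
print(
    "\nEach frame was tumbled by an arbitrary rigid motion before measurement;"
    "\nrecovered angles still equal the applied twist to machine precision because"
    "\nthe N-domain superposition removes global motion exactly in the noise-free case."
)
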