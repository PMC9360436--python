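"""Classify conformational populations across replicate trajectories.

Five replicate runs are simulated from a two-state (inactive/active basin)
Markov process with per-frame switching probabilities p_IA=0.02 and
p_AI=0.03, whose stationary active fraction is p_IA/(p_IA+p_AI) = 0.40.
Frames are classified at the 15-degree threshold and pooled, with a
block-bootstrap confidence interval that respects frame autocorrelation.
"""

import json

from domaintwist import (
    SyntheticConfig,
    bootstrap_ci,
    build_reference,
    build_two_domain_structure,
    domain_selections,
    make_reference_pair,
    population_fractions,
    simulate_trajectory,
    trajectory_angles,
)

runs = []
for seed in range(5):
    config = SyntheticConfig(
        n_atoms_N=30, n_atoms_C=30, p_IA=0.02, p_AI=0.03, n_frames=2000, seed=seed
    )
    structure = build_two_domain_structure(config)
    inactive, active = make_reference_pair(structure, config)
    n_sel, c_sel = domain_selections(config)
    reference = build_reference(inactive, active, n_sel, c_sel)
    ensemble, _ = simulate_trajectory((inactive, active), config)
    runs.append(trajectory_angles(ensemble, reference))

summary = population_fractions(runs, threshold_deg=15.0)
summary.ci95_inactive_like = bootstrap_ci(
    runs, threshold_deg=15.0, n_boot=500, block_len=100, seed=0
)
print(json.dumps(summary.to_dict(system="synthetic two-state"), indent=2))
print(
    f"\nstationary active fraction of the hidden chain: "
    f"{config.stationary_active_fraction:.3f}"
)
print(
    "The classified active-like fraction sits slightly below the hidden-state"
    "\nfraction because the active basin (mean 20 deg, SD 3) leaks ~5% of its"
    "\nframes below the 15-deg threshold; the CI reflects run-to-run and"
    "\nwithin-run (autocorrelated) sampling noise."
)
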