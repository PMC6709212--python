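"""Variable- vs fixed-epoch group inference on synthetic BOLD.

Ground truth: "deliberation" voxels respond for as long as the participant
deliberates (duration-scaled only); "conflict" voxels additionally increase
their amplitude with the per-trial conflict d.  Because RTs rise with
conflict, a fixed-epoch model mistakes time-on-task for conflict modulation;
the variable-epoch model does not.  Inference: per-subject GLM -> PSC maps
-> WLS group F -> TFCE -> permutation FWE -> 20-voxel cluster filter.
"""

import numpy as np

from arcpipe import glm
from arcpipe.design import build_design_matrix
from arcpipe.simulate import simulate_conflict_study

events, bolds, delib, confl = simulate_conflict_study(
    n_subjects=10, n_trials=36, noise_sd=0.25, seed=42
)
print(f"ground truth: {delib.sum()} deliberation-only voxels, "
      f"{confl.sum()} conflict-sensitive voxels (12x12x12 grid)")

for mode in ("variable", "fixed"):
    maps = []
    for bold in bolds:
        info = build_design_matrix(events, n_scans=bold.n_scans, tr=bold.tr,
                                   mode=mode, modulators=("conflict",))
        first = glm.first_level(bold, info)
        maps.append(first.psc("task_conflict",
                              info.matrix["task_conflict"].to_numpy()))
    group = glm.group_inference(np.asarray(maps), n_perms=250, alpha=0.05, seed=0)
    flagged = group.fwe_p <= 0.05
    print(f"\n{mode} epochs: {flagged.sum()} voxels survive FWE at alpha=0.05")
    print(f"  true conflict voxels flagged: {(flagged & confl).sum()}/{confl.sum()}")
    print(f"  deliberation-only voxels flagged (false alarms for 'conflict'): "
          f"{(flagged & delib).sum()}")
    print(f"  surviving clusters (>= 20 voxels): {int(group.labels.max())}")
print("\nfixed epochs flag deliberation voxels too: the time-on-task confound.")
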