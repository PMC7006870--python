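"""Generate a synthetic 20-subject block-design cohort and inspect it.

Each subject is a voxels x volumes BOLD matrix with fROI labels and planted
ground truth: task-active voxels, a strongly coupled 5-fROI core, and
occasional whole-fROI dropout in the peripheral areas.
"""

import numpy as np

from froinet import CohortSpec, canonical_hrf, default_design, simulate_cohort

design = default_design()
kernel = canonical_hrf(design.tr_seconds)
spec = CohortSpec(seed=1)
cohort = simulate_cohort(spec, design, kernel)

print(f"design: {design.n_volumes} volumes at TR={design.tr_seconds}s, "
      f"{len(design.epochs)} epochs of 10s rest / 10s task")
print(f"cohort: {len(cohort)} subjects")
for subject in cohort[:3]:
    n_active = int(subject.truth_active.sum())
    print(f"  {subject.subject_id}: {subject.n_voxels} voxels "
          f"({n_active} truly active) in {len(subject.present_frois)} fROIs")
dropped = [s.subject_id for s in cohort if len(s.present_frois) < len(spec.froi_names)]
print(f"subjects with >= 1 dropped peripheral fROI: {dropped}")
# The dropped subjects emulate individuals whose activation misses an area;
# voxel counts vary per subject because fROI sizes are drawn per subject.
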