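"""k-shell occupancy of the common-network fROIs, with a permutation null.

Core numbers are normalized per subject by that subject's maximal k-core so
shells are comparable across subjects; occupancy counts are pooled. The
null shuffles fROI labels across each subject's voxels (topology fixed) to
ask how much maximal-shell occupancy a fROI of that size shows by chance.
"""

from froinet import (
    CohortSpec, analyze_subject, canonical_hrf, core_decompose, default_design,
    make_regressor, null_occupancy, occupancy_by_froi, simulate_cohort,
)
from froinet.cohort import CORE_FROIS

design = default_design()
kernel = canonical_hrf(design.tr_seconds)
regressor = make_regressor(design, kernel)
cohort = simulate_cohort(CohortSpec(seed=1), design, kernel)

pairs = []
for subject in cohort:
    res = analyze_subject(subject, regressor, theta=0.7)
    if res.vnet is not None and res.vnet.n_edges > 0:
        pairs.append((core_decompose(res.vnet), res.vnet.labels()))

frois = list(CORE_FROIS) + ["angular-gyrus"]
occ = occupancy_by_froi(pairs, froi_filter=frois)
null = null_occupancy(pairs, froi_filter=frois, n_perm=999, seed=7)

print("fROI              max-shell frac   null mean +- sd     perm p")
for froi in frois:
    print(f"{froi:<18s} {occ.max_shell_fraction[froi]:>8.3f}      "
          f"{null.null_mean[froi]:.3f} +- {null.null_sd[froi]:.3f}   {null.p_value[froi]:.4f}")
# Core fROIs sit almost entirely in the maximal shell (fraction near 1, far
# above the null); the peripheral angular gyrus occupies the low shells.
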