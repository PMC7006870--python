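"""Normalized rich-club curves and their robustness to the threshold choice.

phi(k) = 2 E_>k / (N_>k (N_>k - 1)) is normalized by degree-preserving
rewired graphs; a ratio rising above 1 with k means high-degree voxels are
more densely interconnected than their degrees alone require. The sweep
rebuilds the network at theta and at +/- 5% of theta.
"""

from froinet import (
    CohortSpec, analyze_subject, canonical_hrf, default_design,
    make_regressor, simulate_subject, threshold_sensitivity,
)
from froinet.cohort import CORE_FROIS, DEFAULT_CATALOG

design = default_design()
kernel = canonical_hrf(design.tr_seconds)
regressor = make_regressor(design, kernel)

# a reduced subject keeps the rewiring nulls quick
catalog = tuple((n, (8, 12)) if n in CORE_FROIS else (n, (6, 10)) for n, _ in DEFAULT_CATALOG)
subject = simulate_subject(CohortSpec(froi_catalog=catalog, seed=5), design, kernel, 0)
res = analyze_subject(subject, regressor, theta=0.7)
mask = res.amap.active

sweep = threshold_sensitivity(
    subject.bold[mask], subject.labels[mask], theta0=0.7, n_null=50, seed=11
)
for delta in sorted(sweep.curves):
    curve = sweep.curves[delta]
    frame = curve.to_frame().dropna()
    tail = frame.tail(3)
    print(f"delta={delta:+.2f}: slope of ratio vs k = {sweep.slopes[delta]:+.4f}; "
          f"ratio at top k: {tail['ratio'].round(2).tolist()}")
print(f"qualitative agreement across thresholds: {sweep.qualitative_agreement}")
# Positive slopes at all three thresholds: the rich-club organization of the
# planted core is not an artifact of the particular correlation cutoff.
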