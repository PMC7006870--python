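# Methods

This note documents the models, parameter choices, and numerical policies
behind froinet, and what the synthetic cohort does and does not emulate.

## Task design and regressor

The default design is six 20 s epochs, each 10 s rest + 10 s task, sampled
at TR = 2 s (60 volumes). TR = 2 s is chosen so that the 10 s sub-blocks
align to whole volumes; clinical protocols with TR = 4 s would put 2.5
volumes in a sub-block, and fractional-volume handling adds nothing to the
downstream graph analysis. The 0/1 boxcar is convolved with a double-gamma
HRF (peak 6 s, undershoot 16 s, dispersions 1 s, undershoot ratio 1/6,
truncated at 32 s, peak-normalized to 1). These are the conventional
canonical-HRF defaults; all are configurable through `HRFSpec`. The
regressor is the exact linear convolution, truncated to the run length. It
is *not* clipped at zero: the undershoot makes the true linear response dip
slightly negative after block offsets, and clipping would bias the
activation statistic.

## Synthetic cohort generative model

For voxel `v` in fROI `f`:

    x_v(t) = β_v r(t) + ρ_w g_f(t) + ρ_c h(t)·[f ∈ core] + ε_v(t)

with `r` the regressor rescaled to peak 1, `g_f = r + η_f` a per-fROI
latent, `h = r + η_h` one latent shared by the five core fROIs, η and ε
white Gaussian (latent SD 1, noise SD σ). β_v = β for active voxels and 0
for the planted-inactive fraction. The latent-factor form guarantees a
positive-semidefinite covariance and O(voxels) generation, and makes all
planted couplings non-negative — matching the empirical situation in
task-locked data where supra-threshold correlations are positive.

Defaults (chosen analytically once, before any end-to-end run, from the
population-correlation targets below; units are arbitrary signal units):

| parameter | default | role |
|---|---|---|
| β (beta_active) | 1.8 | task amplitude of active voxels |
| σ (sigma_noise) | 1.0 | i.i.d. voxel noise SD |
| ρ_w (rho_within) | 1.0 | within-fROI shared-factor loading |
| ρ_c (rho_core) | 2.5 | extra loading shared by core fROIs |
| fraction_inactive | 0.2 | voxels with β = 0 |
| p_dropout | 0.1 | per-subject absence of a non-obligatory fROI |
| n_subjects | 20 | cohort size |

With regressor variance ≈ 0.16, these give population correlations of
≈ 0.6 between an active voxel and the regressor (detection power > 0.9 at
one-sided p < 10⁻⁴ with 60 volumes, roughly a d ≈ 1.5 block effect),
≈ 0.85 between voxels in different core fROIs (above θ = 0.7, so core
links are essentially always present), and ≈ 0.40 between voxels of
different peripheral fROIs (well below θ, so peripheral links are
non-persistent). The planted structure is therefore separable *by design*;
the tests verify that the pipeline recovers exactly it, not more.

The catalog has 5 core fROIs (20–35 voxels) and 7 peripheral fROIs (12–28
voxels), ≈ 290 voxels per subject. Dropout removes whole non-obligatory
fROIs: the default obligatory set equals the core, so the common network
has a well-defined planted truth at presence 0.85. Cohorts in which core
areas themselves go missing in a few subjects (as happens in real data)
are generated by shrinking `obligatory_frois` in the `CohortSpec`.

What the generator does **not** emulate: spatial geometry and smoothing,
motion and physiological noise, autocorrelated (AR) noise, hemispheric
structure, scanner drift. Passing tests therefore demonstrate the
correctness of the graph pipeline under a clean factor model, not
robustness to real-scanner artifacts; the activation calibration test uses
white-noise nulls, which is exact for the t-transform but optimistic for
autocorrelated BOLD noise.

## Activation mapping

The statistic is the Pearson correlation of each voxel with the regressor
(equivalent to the slope test of a GLM with one regressor plus intercept),
one-sided for positive association; a two-sided flag exists. Constant
(zero-variance) voxels get r = 0, p = 1 and a warning rather than NaNs.
BH q-values come from `statsmodels` and are verified in tests against a
brute-force implementation of the step-up definition. An fROI exclusion
list (the visual/auditory-cortex analog) removes areas active for
non-linguistic reasons after the statistic, before network construction.

## Network construction

θ is an explicit, required parameter (default 0.7): the threshold that
turns correlations into links is the one genuinely free constant of the
analysis, so it is surfaced and swept (±5 %) rather than hidden. The edge
rule is `C_ij ≥ θ` on signed correlations — negative edges are excluded,
not rectified — and ties at exactly θ are included, which keeps the edge
set a deterministic function of the correlation matrix. Isolated active
voxels stay in the network and count toward fROI sizes, so the Eq-style
weight `W = #cross-links / (size_i + size_j)` uses sizes equal to node
counts. Subjects whose fROI network is edgeless are excluded from the
group stage with a warning.

## Group analysis

The presence rule uses `ceil(presence_fraction × N)` with default 0.85
(17 of 20). Link weights average over the subjects possessing the link
(sample SD, ddof = 1; a single possessor reports SD 0 and is flagged by
`n_present = 1`); dividing the sum by the full N instead is available as
`denominator="all"`. Node- and link-presence are counted independently; an
fROI is kept only with ≥ 1 retained incident link, so the common network
never contains isolated areas. Weights are sorted before averaging so the
result is exactly invariant under subject reordering.

## k-core occupancy

Core numbers come from the standard iterative-pruning decomposition
(`networkx.core_number`) on the full voxel graph including within-fROI
edges; they are order-independent and topology-only. Normalization divides
by the per-subject `kcore_max`, mapping each subject's deepest shell to 1.
Occupancy uses 10 equal-width right-closed bins on (0, 1], with the lowest
bin extended to include 0 so that isolated voxels (core number 0) are
counted rather than dropped — dropping them would overstate the top-shell
occupancy of weakly connected fROIs. The null model shuffles fROI labels
across each subject's nodes (preserving per-subject topology and fROI
sizes), pools exactly as the observed histogram, and reports the two-sided
add-one permutation p-value `(1 + #{|null − mean| ≥ |obs − mean|}) /
(n_perm + 1)`, which cannot return 0 at finite n_perm.

## Rich club

φ(k) uses degrees measured in the original graph for the `> k` filter (the
standard convention; computed in O(E + k_max) from the min endpoint degree
per edge). The null is double-edge-swap rewiring with rejection of
self-loops/multi-edges, default 10 × E attempted swaps and 100 null
replicates — common mixing heuristics, both configurable. Graphs with no
admissible swap (complete graphs, < 2 edges) are returned unchanged with a
warning. Ratios are reported only where the null mean is positive and
N_>k ≥ 2; undefined points are omitted, never zero-filled. The threshold
sweep rebuilds the network at θ(1 ± 0.05) and summarizes each curve by the
sign of the least-squares slope of ratio vs k; agreement of signs across
the three thresholds is the qualitative-robustness flag.

## Problem sizes used in tests

The test suite and acceptance checks run at deliberately modest sizes
chosen as the smallest scales at which each property is statistically
sharp: oracle equivalences on 200 random graphs (n ≤ 12); activation
calibration on 10⁵ null voxels; planted-core recovery on 20 replicate
20-subject cohorts (~290 voxels each, 199-permutation nulls); rich-club
checks on n ≈ 120–200 graphs with 30–50 rewired nulls and a reduced
(~90-voxel) subject for the ±5 % sweep. The pipeline itself has no such
limits; all replication counts are parameters.

## Seeds and determinism

Every stochastic step derives its RNG from a master seed plus a stable
string label (`_rng.rng_for`); no global RNG state is used. Identical
configs give bit-identical cohorts, reports, and output files.

## Known limitations

- Correlations are computed over the full run, not task blocks only.
- No partial correlations, frequency-band connectivity, or weighted
  (s-core) decomposition; negative edges are excluded, not modeled.
- The activation stage assumes preprocessed (motion-corrected, detrended)
  input; no preprocessing is performed.
- External data enter through per-subject TSVs; no NIfTI/DICOM ingestion.
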