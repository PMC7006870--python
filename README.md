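# froinet

Functional network analysis for block-design task fMRI: from per-subject
BOLD time series to voxel-level correlation networks, fROI-level weighted
graphs, a cross-subject **common network**, **k-core/k-shell** occupancy
with permutation nulls, and **normalized rich-club** curves. A synthetic
cohort generator with planted ground truth makes every stage testable
without scanner data.

The package is aimed at researchers studying group-persistent functional
circuits — e.g. the language network mapped before neurosurgery — who need
a reproducible, scriptable pipeline from activation maps to graph-level
statistics.

## The model

**Activation.** Each voxel's series is correlated with the HRF-convolved
boxcar task regressor; with `t = r·√(n−2)/√(1−r²)` on `n−2` df, voxels with
one-sided `p < 10⁻⁴` are active (Benjamini–Hochberg q-values are reported
as an FDR diagnostic, `q < 10⁻³`).

**Voxel network.** Nodes are active voxels; an undirected link joins `i, j`
whenever the Pearson correlation

&nbsp;&nbsp;&nbsp;&nbsp;`C_ij = (⟨x_i x_j⟩ − ⟨x_i⟩⟨x_j⟩) / (σ_i σ_j)`

reaches an absolute threshold θ (default 0.7), with weight `C_ij`.

**fROI network.** fROIs `i, j` are linked iff ≥ 1 voxel link crosses
between them, with weight

&nbsp;&nbsp;&nbsp;&nbsp;`W_ij = #links(i↔j) / (size_i + size_j)`,&nbsp;&nbsp;
`W̃_ij = W_ij / W^max` per subject,

so `max W̃ = 1` in every individual network.

**Common network.** A link (and its fROIs) is retained iff present in
≥ ⌈presence_fraction · N⌉ subjects (default 0.85, i.e. 17/20); its weight
`W^C` is the mean of `W̃` over the subjects possessing it, ± SD.

**k-core occupancy.** Per-subject core numbers are normalized by the
subject's `kcore_max`; pooled per-fROI shell histograms are compared with a
label-shuffling null (topology fixed) to test maximal-shell enrichment.

**Rich club.** `φ(k) = 2E_{>k} / (N_{>k}(N_{>k}−1))` normalized by
degree-preserving rewired graphs, plus a ±5 % threshold-sensitivity sweep.

## Worked example

```sh
python examples/03_common_network.py
```

prints (seed 1, 20 synthetic subjects, θ = 0.7, presence 0.85):

```
common network (20 subjects, presence >= 17):
 froi_i  froi_j      W_C       sd  n_present
     WA   op-BA 0.838385 0.150313         20
     WA pre-SMA 0.841705 0.096620         20
     ...
  preMA  tri-BA 0.857266 0.109357         20
```

The recovered node set {op-BA, tri-BA, WA, preMA, pre-SMA} is exactly the
planted strongly coupled core; `W_C` is the mean normalized weight across
the possessing subjects and `n_present` the number of subjects carrying the
link. `examples/04_kshell_occupancy.py` then shows the core fROIs sitting
almost entirely in the maximal k-shell (occupancy ≈ 0.96–1.00 against a
null of ≈ 0.53, permutation p = 0.001), while the peripheral angular gyrus
occupies the low shells; `examples/05_rich_club.py` shows the normalized
rich-club ratio rising above 1 with k at θ and at θ ± 5 %.

Each `examples/0*.py` script covers one capability (cohort generation,
single-subject networks, group analysis, k-shell occupancy, rich club) and
prints what the numbers mean. A thin CLI wraps the same functions:
`froinet simulate|activate|network|common|run|richclub-sweep --help`.

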