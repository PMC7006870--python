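"""Synthetic multi-subject BOLD cohorts with planted network structure.

Generative model
----------------
For voxel ``v`` in fROI ``f`` of one subject,

    x_v(t) = beta_v * r(t) + rho_within * g_f(t)
             + rho_core * h(t)   [only if f is a planted-core fROI]
             + eps_v(t)

where ``r`` is the HRF-convolved task regressor rescaled to peak 1,
``g_f = r + eta_f`` is a per-fROI latent series, ``h = r + eta_h`` is a
single latent shared by all core fROIs (eta terms are unit-variance white
noise), and ``eps_v`` is i.i.d. Gaussian(0, sigma_noise^2). ``beta_v`` equals
``beta_active`` for active voxels and 0 for the planted-inactive fraction.

Because every latent carries the regressor, all planted couplings are
non-negative: within-fROI voxels share ``g_f``, core voxels additionally
share ``h`` (the strongly coupled planted core), and voxels in different
non-core fROIs correlate only through the common task response. Per-subject
fROI dropout removes whole non-obligatory fROIs with probability
``p_dropout``, emulating subjects whose activation misses an area entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import rng_for
from .design import TaskDesign, canonical_hrf, default_design, make_regressor
from .errors import InvalidSpecError

__all__ = [
    "CORE_FROIS",
    "DEFAULT_CATALOG",
    "CohortSpec",
    "SubjectData",
    "simulate_subject",
    "simulate_cohort",
]

#: The five fROIs planted as the strongly coupled core (the language-network
#: analog: opercular/triangular Broca, Wernicke, premotor, pre-SMA).
CORE_FROIS: tuple[str, ...] = ("op-BA", "tri-BA", "WA", "preMA", "pre-SMA")

#: Default fROI catalog: (name, (min_voxels, max_voxels)). Core areas are
#: somewhat larger; seven peripheral areas round the cohort out to roughly
#: 300 voxels per subject.
DEFAULT_CATALOG: tuple[tuple[str, tuple[int, int]], ...] = (
    ("op-BA", (20, 35)),
    ("tri-BA", (20, 35)),
    ("WA", (20, 35)),
    ("preMA", (20, 35)),
    ("pre-SMA", (20, 35)),
    ("angular-gyrus", (12, 28)),
    ("supramarginal-gyrus", (12, 28)),
    ("precentral-gyrus", (12, 28)),
    ("aMFG", (12, 28)),
    ("DOC", (12, 28)),
    ("d-preMA", (12, 28)),
    ("caudate", (12, 28)),
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``obligatory_frois`` are never dropped; by default this is the planted
    core, so dropout (probability ``p_dropout`` per subject and fROI) acts on
    the peripheral catalog entries. To emulate subjects missing a core area,
    pass a smaller obligatory set.
    """

    n_subjects: int = 20
    froi_catalog: tuple[tuple[str, tuple[int, int]], ...] = DEFAULT_CATALOG
    core_frois: tuple[str, ...] = CORE_FROIS
    beta_active: float = 1.8
    sigma_noise: float = 1.0
    rho_within: float = 1.0
    rho_core: float = 2.5
    p_dropout: float = 0.1
    fraction_inactive: float = 0.2
    seed: int = 0
    obligatory_frois: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidSpecError("n_subjects must be >= 1")
        if len(self.froi_catalog) == 0:
            raise InvalidSpecError("froi_catalog must not be empty")
        names = [name for name, _ in self.froi_catalog]
        if len(set(names)) != len(names):
            raise InvalidSpecError("froi_catalog names must be unique")
        for name, (lo, hi) in self.froi_catalog:
            if lo < 1 or hi < lo:
                raise InvalidSpecError(f"bad voxel_count_range for {name}: ({lo}, {hi})")
        if not set(self.core_frois) <= set(names):
            raise InvalidSpecError("core_frois must be a subset of catalog names")
        if not (0.0 <= self.p_dropout <= 1.0):
            raise InvalidSpecError("p_dropout must lie in [0, 1]")
        if not (0.0 <= self.fraction_inactive <= 1.0):
            raise InvalidSpecError("fraction_inactive must lie in [0, 1]")
        if self.sigma_noise < 0:
            raise InvalidSpecError("sigma_noise must be >= 0")
        if self.rho_within < 0 or self.rho_core < 0:
            raise InvalidSpecError("latent loadings must be >= 0")
        if self.obligatory_frois is not None and not set(self.obligatory_frois) <= set(names):
            raise InvalidSpecError("obligatory_frois must be a subset of catalog names")

    @property
    def obligatory(self) -> frozenset[str]:
        if self.obligatory_frois is None:
            return frozenset(self.core_frois)
        return frozenset(self.obligatory_frois)

    @property
    def froi_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.froi_catalog)


@dataclass
class SubjectData:
    """One subject: BOLD matrix (voxels x volumes) plus voxel metadata.

    ``truth_active``/``truth_beta`` carry the planted ground truth and are
    ``None`` for subjects read from external files without a sidecar.
    """

    subject_id: str
    bold: np.ndarray
    labels: np.ndarray  # per-voxel fROI name (str array)
    voxel_ids: np.ndarray | None = None  # defaults to 0..n_voxels-1
    truth_active: np.ndarray | None = None
    truth_beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.bold.ndim != 2:
            raise InvalidSpecError("bold must be a 2-D voxels x volumes matrix")
        if self.bold.shape[0] != self.labels.shape[0]:
            raise InvalidSpecError("bold row count must equal number of labels")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.bold.shape[0])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.shape[0] != self.bold.shape[0]:
                raise InvalidSpecError("voxel_ids length must equal bold row count")
        for arr_name in ("truth_active", "truth_beta"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape[0] != self.bold.shape[0]:
                    raise InvalidSpecError(f"{arr_name} length must equal bold row count")
                setattr(self, arr_name, arr)

    @property
    def n_voxels(self) -> int:
        return self.bold.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[1]

    @property
    def present_frois(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return tuple(seen)


def _scaled_regressor(design: TaskDesign, kernel: np.ndarray) -> np.ndarray:
    r = make_regressor(design, kernel)
    peak = np.abs(r).max()
    return r / peak if peak > 0 else r


def simulate_subject(
    spec: CohortSpec,
    design: TaskDesign,
    kernel: np.ndarray,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectData:
    """Simulate one subject under the latent-factor generative model.

    Reproducible: identical ``(spec.seed, subject_seed)`` give bit-identical
    output.
    """
    rng = rng_for(spec.seed, "subject", subject_seed)
    n_vol = design.n_volumes
    r = _scaled_regressor(design, kernel)

    # Core latent is drawn unconditionally so that the random stream (and
    # hence all other draws) does not depend on which fROIs survive dropout.
    h = r + rng.standard_normal(n_vol)
    drop = {
        name: (name not in spec.obligatory and rng.random() < spec.p_dropout)
        for name in spec.froi_names
    }

    rows: list[np.ndarray] = []
    labels: list[str] = []
    active_flags: list[np.ndarray] = []
    betas: list[np.ndarray] = []
    core = set(spec.core_frois)
    for name, (lo, hi) in spec.froi_catalog:
        n_vox = int(rng.integers(lo, hi + 1))
        g = r + rng.standard_normal(n_vol)
        active = rng.random(n_vox) >= spec.fraction_inactive
        eps = rng.standard_normal((n_vox, n_vol)) * spec.sigma_noise
        if drop[name]:
            continue
        beta = np.where(active, spec.beta_active, 0.0)
        x = beta[:, None] * r[None, :] + spec.rho_within * g[None, :] + eps
        if name in core:
            x = x + spec.rho_core * h[None, :]
        rows.append(x)
        labels.extend([name] * n_vox)
        active_flags.append(active)
        betas.append(beta)

    if not rows:  # every fROI dropped (possible only with p_dropout = 1)
        bold = np.empty((0, n_vol))
        active_all = np.empty(0, dtype=bool)
        beta_all = np.empty(0)
    else:
        bold = np.vstack(rows)
        active_all = np.concatenate(active_flags)
        beta_all = np.concatenate(betas)
    return SubjectData(
        subject_id=subject_id or f"sub-{subject_seed:02d}",
        bold=bold,
        labels=np.array(labels, dtype=object),
        truth_active=active_all,
        truth_beta=beta_all,
    )


def simulate_cohort(
    spec: CohortSpec,
    design: TaskDesign | None = None,
    kernel: np.ndarray | None = None,
) -> list[SubjectData]:
    """Simulate ``spec.n_subjects`` subjects with deterministically derived seeds."""
    design = design or default_design()
    if kernel is None:
        kernel = canonical_hrf(design.tr_seconds)
    return [
        simulate_subject(spec, design, kernel, subject_seed=i, subject_id=f"sub-{i + 1:02d}")
        for i in range(spec.n_subjects)
    ]
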