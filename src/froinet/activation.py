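"""Per-voxel activation mapping against the task regressor.

Each voxel's BOLD series is tested for association with the HRF-convolved
task regressor using the Pearson correlation ``r`` and its t-transform
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` on ``n - 2`` degrees of freedom.
For a single regressor plus intercept this is equivalent to the GLM slope
test. The test is one-sided for positive association by default (activated
voxels are those positively locked to the stimulus); a two-sided variant is
available by flag. Benjamini-Hochberg q-values control the FDR across the
voxels of one subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import SubjectData
from .errors import UndefinedCorrelationError

__all__ = [
    "ActivationMap",
    "voxel_statistic",
    "bh_qvalues",
    "activation_map",
    "select_active",
]

DEFAULT_P_THRESH = 1e-4
DEFAULT_Q_THRESH = 1e-3


@dataclass
class ActivationMap:
    """Per-voxel activation statistics for one subject."""

    voxel_ids: np.ndarray
    froi: np.ndarray
    r: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    active: np.ndarray
    p_thresh: float
    q_thresh: float
    subject_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": self.voxel_ids,
                "froi": self.froi,
                "r": self.r,
                "p": self.p_value,
                "q": self.q_value,
                "active": self.active,
            }
        )


def _pearson_with_p(
    rows: np.ndarray, y: np.ndarray, two_sided: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson r of each row against y, with t-transform p-values.

    Returns (r, p, constant_mask); constant rows get r = 0, p = 1 by policy.
    """
    n = rows.shape[1]
    yc = y - y.mean()
    y_ss = float(yc @ yc)
    if y_ss == 0.0:
        raise UndefinedCorrelationError("regressor is constant")
    rc = rows - rows.mean(axis=1, keepdims=True)
    row_ss = np.einsum("ij,ij->i", rc, rc)
    constant = row_ss == 0.0
    denom = np.sqrt(np.where(constant, 1.0, row_ss) * y_ss)
    r = (rc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    df = n - 2
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    else:
        p = stats.t.sf(t, df)
        p = np.where(r >= 1.0, 0.0, np.where(r <= -1.0, 1.0, p))
    p = np.clip(p, 0.0, 1.0)
    r = np.where(constant, 0.0, r)
    p = np.where(constant, 1.0, p)
    return r, p, constant


def voxel_statistic(
    bold_row: np.ndarray, regressor: np.ndarray, two_sided: bool = False
) -> tuple[float, float]:
    """Pearson r of one voxel against the regressor plus its p-value.

    Raises :class:`UndefinedCorrelationError` for constant inputs; batch
    callers handle the case by assigning p = 1 (see :func:`activation_map`).
    """
    x = np.asarray(bold_row, dtype=float)
    y = np.asarray(regressor, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("bold_row and regressor must be 1-D and equal length")
    if x.size < 4:
        raise ValueError("need at least 4 time points")
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("bold_row is constant")
    r, p, _ = _pearson_with_p(x[None, :], y, two_sided=two_sided)
    return float(r[0]), float(p[0])


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def activation_map(
    subject: SubjectData,
    regressor: np.ndarray,
    p_thresh: float = DEFAULT_P_THRESH,
    q_thresh: float = DEFAULT_Q_THRESH,
    two_sided: bool = False,
    exclude_frois: tuple[str, ...] = (),
) -> ActivationMap:
    """Compute r, p, BH q, and the active flag for every voxel of a subject.

    Constant (zero-variance) voxels are assigned p = 1 and reported inactive,
    with a warning. Voxels in ``exclude_frois`` (the visual/auditory-cortex
    analog) are flagged inactive regardless of their statistic.
    """
    y = np.asarray(regressor, dtype=float)
    if subject.n_volumes != y.size:
        raise ValueError("regressor length must equal the number of volumes")
    if subject.n_volumes < 4:
        raise ValueError("need at least 4 volumes")
    r, p, constant = _pearson_with_p(subject.bold, y, two_sided=two_sided)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant voxel(s) assigned p = 1 and excluded",
            stacklevel=2,
        )
    q = bh_qvalues(p)
    active = p < p_thresh
    if exclude_frois:
        excluded = np.isin(subject.labels.astype(str), list(exclude_frois))
        active = active & ~excluded
    return ActivationMap(
        voxel_ids=np.asarray(subject.voxel_ids),
        froi=subject.labels.astype(str),
        r=r,
        p_value=p,
        q_value=q,
        active=active,
        p_thresh=p_thresh,
        q_thresh=q_thresh,
        subject_id=subject.subject_id,
    )


def select_active(amap: ActivationMap, p_thresh: float | None = None) -> tuple[np.ndarray, bool]:
    """Active voxel ids plus an FDR diagnostic flag.

    The flag reports whether the largest q-value among the selected voxels is
    below the map's q threshold (no selection counts as passing vacuously).
    """
    thresh = amap.p_thresh if p_thresh is None else p_thresh
    mask = (amap.p_value < thresh) & amap.active if p_thresh is None else (amap.p_value < thresh)
    ids = amap.voxel_ids[mask]
    fdr_ok = bool(mask.sum() == 0 or amap.q_value[mask].max() < amap.q_thresh)
    return ids, fdr_ok
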