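"""Block task designs, the canonical HRF, and the task regressor.

A block ("boxcar") design alternates rest and stimulation periods. The BOLD
response to the stimulation train is modelled by convolving the 0/1 boxcar
with a double-gamma hemodynamic response function (HRF) sampled at the
repetition time (TR); the convolved series is the single task regressor used
both by the synthetic generator and by the activation-mapping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidDesignError, InvalidSpecError

__all__ = [
    "TaskDesign",
    "HRFSpec",
    "default_design",
    "make_boxcar",
    "canonical_hrf",
    "make_regressor",
]


@dataclass(frozen=True)
class TaskDesign:
    """A block design given as ordered (rest_volumes, task_volumes) epochs.

    The default constructed by :func:`default_design` is six epochs of
    5 rest + 5 task volumes at TR = 2 s, i.e. six 20 s epochs with 10 s
    off / 10 s on, aligned to whole volumes.
    """

    epochs: tuple[tuple[int, int], ...]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise InvalidDesignError("design must contain at least one epoch")
        for rest, task in self.epochs:
            if rest < 0 or task < 0 or (rest + task) == 0:
                raise InvalidDesignError(
                    f"epoch ({rest}, {task}) must have non-negative counts and >= 1 volume"
                )
        if not self.tr_seconds > 0:
            raise InvalidDesignError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return sum(r + t for r, t in self.epochs)

    @property
    def boxcar(self) -> np.ndarray:
        return make_boxcar(self)


def default_design() -> TaskDesign:
    """Six 20 s epochs (10 s rest, 10 s task) at TR = 2 s: 60 volumes."""
    return TaskDesign(epochs=tuple([(5, 5)] * 6), tr_seconds=2.0)


def make_boxcar(design: TaskDesign) -> np.ndarray:
    """0/1 task indicator over volumes: 0 during rest, 1 during task blocks."""
    parts: list[np.ndarray] = []
    for rest, task in design.epochs:
        parts.append(np.zeros(rest, dtype=float))
        parts.append(np.ones(task, dtype=float))
    return np.concatenate(parts)


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF parameters (seconds).

    Defaults follow the common convention: response peaking near 6 s, an
    undershoot near 16 s with relative amplitude 1/6, kernel truncated at
    32 s. The sampled kernel is peak-normalized to 1.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion_s",
            "undershoot_dispersion_s",
            "kernel_length_s",
        ):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.undershoot_ratio < 0:
            raise InvalidSpecError("undershoot_ratio must be non-negative")


def hrf_curve(t: np.ndarray, spec: HRFSpec) -> np.ndarray:
    """The (un-normalized) double-gamma curve evaluated at times ``t`` >= 0."""
    peak = stats.gamma.pdf(
        t, a=spec.peak_delay_s / spec.peak_dispersion_s, scale=spec.peak_dispersion_s
    )
    under = stats.gamma.pdf(
        t,
        a=spec.undershoot_delay_s / spec.undershoot_dispersion_s,
        scale=spec.undershoot_dispersion_s,
    )
    return peak - spec.undershoot_ratio * under


def canonical_hrf(tr_seconds: float, spec: HRFSpec | None = None) -> np.ndarray:
    """Sample the double-gamma HRF at TR spacing, peak-normalized to 1.

    The kernel is identically zero for negative lags (causal) and truncated
    at ``spec.kernel_length_s``.
    """
    if not tr_seconds > 0:
        raise InvalidSpecError("tr_seconds must be positive")
    spec = spec or HRFSpec()
    t = np.arange(0.0, spec.kernel_length_s, tr_seconds)
    kernel = hrf_curve(t, spec)
    peak = kernel.max()
    if not peak > 0:
        raise InvalidSpecError("HRF kernel has no positive peak; check the spec")
    return kernel / peak


def make_regressor(design: TaskDesign, kernel: np.ndarray) -> np.ndarray:
    """Linear convolution of the boxcar with the HRF kernel, truncated.

    Note the double-gamma undershoot makes the exact convolution dip
    slightly below zero after block offsets; the regressor is left
    unclipped so that it is the true linear response to the block train.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size == 0:
        raise InvalidSpecError("kernel must be a non-empty 1-D array")
    boxcar = make_boxcar(design)
    if kernel.size > boxcar.size:
        raise InvalidDesignError(
            f"kernel length {kernel.size} exceeds n_volumes {boxcar.size}"
        )
    return np.convolve(boxcar, kernel)[: boxcar.size]
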