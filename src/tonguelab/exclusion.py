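"""Removal of dark-root and specular pixels by L* thresholding.

Two kinds of pixels inside the segmented tongue carry no usable color: the
dark band at the tongue root (low illumination, L* under 30) and specular
reflections from saliva (L* over 85).  Both are excluded by lightness
thresholds; equality at a threshold is *retained* (exclusion is strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import LabRaster
from .errors import DomainError, FormatError
from .segmentation import TongueMask

__all__ = ["ExclusionParams", "ExclusionReport", "valid_pixel_mask"]


@dataclass(frozen=True)
class ExclusionParams:
    dark_threshold: float = 30.0
    bright_threshold: float = 85.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dark_threshold < self.bright_threshold <= 100.0):
            raise DomainError(
                "thresholds must satisfy 0 <= dark < bright <= 100, got "
                f"({self.dark_threshold}, {self.bright_threshold})"
            )


@dataclass(frozen=True)
class ExclusionReport:
    """Pixel bookkeeping: removed_dark + removed_bright + retained = tongue."""

    retained: int
    removed_dark: int
    removed_bright: int

    @property
    def total(self) -> int:
        return self.retained + self.removed_dark + self.removed_bright

    def as_dict(self) -> dict:
        tot = max(self.total, 1)
        return {
            "retained": self.retained,
            "removed_dark": self.removed_dark,
            "removed_bright": self.removed_bright,
            "fraction_dark": self.removed_dark / tot,
            "fraction_bright": self.removed_bright / tot,
        }


def valid_pixel_mask(
    lab: LabRaster,
    tongue: TongueMask,
    params: ExclusionParams | None = None,
) -> tuple[TongueMask, ExclusionReport]:
    """Retain tongue pixels with dark_threshold <= L* <= bright_threshold.

    Returns the validity sub-mask (same provenance as the input mask) and a
    per-cause removal report.
    """
    params = params or ExclusionParams()
    if tongue.mask.shape != lab.shape:
        raise FormatError("tongue mask and Lab raster shapes differ")
    L = np.asarray(lab.L, dtype=float)
    dark = tongue.mask & (L < params.dark_threshold)
    bright = tongue.mask & (L > params.bright_threshold)
    valid = tongue.mask & ~dark & ~bright
    report = ExclusionReport(
        retained=int(valid.sum()),
        removed_dark=int(dark.sum()),
        removed_bright=int(bright.sum()),
    )
    return TongueMask(mask=valid, provenance=tongue.provenance), report
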