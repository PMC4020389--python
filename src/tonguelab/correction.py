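"""Checker-based affine color correction in CIELAB.

A 12-patch color checker is photographed with every tongue image.  Six
achromatic (gray) patches calibrate lightness and six chromatic patches
calibrate the opponent axes: one affine map per coordinate,

    L' = alpha_L * L + beta_L        (fit on the 6 achromatic patches)
    a' = alpha_a * a + beta_a        (fit on the 6 chromatic patches)
    b' = alpha_b * b + beta_b        (fit on the 6 chromatic patches)

each solved by ordinary least squares of the *reference* values on the
*measured* patch means.  An optional full 3x3 cross-channel fit (all 12
patches, one linear map plus offset across L, a, b jointly) is available for
devices with channel cross-talk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import LabRaster
from .errors import FitError, FormatError

__all__ = [
    "CheckerPatch",
    "CheckerSet",
    "CorrectionModel",
    "sample_checker",
    "fit_correction",
    "apply_correction",
]

_COORDS = ("L", "a", "b")


@dataclass(frozen=True)
class CheckerPatch:
    patch_id: str
    role: str  # "achromatic" | "chromatic"
    reference: tuple[float, float, float]  # (L, a, b)
    measured: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.role not in ("achromatic", "chromatic"):
            raise FormatError(f"patch role must be achromatic|chromatic, got {self.role!r}")
        if not all(np.isfinite(self.measured)):
            raise FormatError(f"patch {self.patch_id}: non-finite measured value")


@dataclass(frozen=True)
class CheckerSet:
    """The 12 paired (measured, reference) Lab triples of one image."""

    patches: tuple[CheckerPatch, ...]

    def __post_init__(self) -> None:
        roles = [p.role for p in self.patches]
        if len(self.patches) != 12 or roles.count("achromatic") != 6:
            raise FormatError(
                "checker must hold exactly 6 achromatic and 6 chromatic patches"
            )

    def subset(self, role: str) -> list[CheckerPatch]:
        return [p for p in self.patches if p.role == role]


@dataclass(frozen=True)
class CorrectionModel:
    """Fitted per-coordinate affine maps and their residual sums of squares."""

    slope: dict[str, float]
    intercept: dict[str, float]
    rss: dict[str, float]
    matrix: np.ndarray | None = None  # optional 3x3 cross-channel map
    offset: np.ndarray | None = None

    @classmethod
    def identity(cls) -> "CorrectionModel":
        one = {c: 1.0 for c in _COORDS}
        zero = {c: 0.0 for c in _COORDS}
        return cls(slope=one, intercept=zero, rss=dict(zero))

    def warn_if_implausible(self) -> list[str]:
        msgs = []
        for c in _COORDS:
            if self.slope[c] <= 0:
                msgs.append(f"non-positive slope for {c}: {self.slope[c]:.4g}")
        return msgs

    def as_dict(self) -> dict:
        d = {
            "slope": dict(self.slope),
            "intercept": dict(self.intercept),
            "rss": dict(self.rss),
        }
        if self.matrix is not None:
            d["matrix"] = self.matrix.tolist()
            d["offset"] = self.offset.tolist()
        return d


def sample_checker(
    lab: LabRaster,
    patch_regions: list[tuple[int, int, int, int]],
    references: list[tuple[float, float, float]],
    roles: list[str],
    patch_ids: list[str] | None = None,
) -> CheckerSet:
    """Measure each checker patch as its per-region mean Lab.

    ``patch_regions`` are (row0, col0, height, width) rectangles; they must
    lie inside the image, not overlap, and span at least 4 pixels each.
    """
    h, w = lab.shape
    if not (len(patch_regions) == len(references) == len(roles) == 12):
        raise FormatError("exactly 12 regions, references and roles required")
    occupancy = np.zeros((h, w), dtype=bool)
    patches = []
    ids = patch_ids or [f"P{i + 1:02d}" for i in range(12)]
    for pid, (r0, c0, ph, pw), ref, role in zip(ids, patch_regions, references, roles):
        if r0 < 0 or c0 < 0 or r0 + ph > h or c0 + pw > w:
            raise FormatError(f"patch {pid}: region outside image")
        if ph * pw < 4:
            raise FormatError(f"patch {pid}: region smaller than 4 px")
        if occupancy[r0 : r0 + ph, c0 : c0 + pw].any():
            raise FormatError(f"patch {pid}: region overlaps another patch")
        occupancy[r0 : r0 + ph, c0 : c0 + pw] = True
        measured = (
            float(lab.L[r0 : r0 + ph, c0 : c0 + pw].mean()),
            float(lab.a[r0 : r0 + ph, c0 : c0 + pw].mean()),
            float(lab.b[r0 : r0 + ph, c0 : c0 + pw].mean()),
        )
        patches.append(
            CheckerPatch(patch_id=pid, role=role, reference=tuple(ref), measured=measured)
        )
    return CheckerSet(patches=tuple(patches))


def _affine_lsq(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS fit y ~ slope*x + intercept via the normal equations."""
    if np.ptp(x) == 0:
        raise FitError("degenerate design: all measured values equal")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_correction(checker: CheckerSet, cross_channel: bool = False) -> CorrectionModel:
    """Least-squares fit of the correction from measured to reference Lab.

    Achromatic patches determine the L* map; chromatic patches determine the
    a* and b* maps.  With ``cross_channel=True`` a single affine 3x3 map is
    fit on all 12 patches instead.
    """
    if cross_channel:
        M = np.array([p.measured for p in checker.patches])
        R = np.array([p.reference for p in checker.patches])
        A = np.column_stack([M, np.ones(len(M))])
        coef, *_ = np.linalg.lstsq(A, R, rcond=None)
        resid = R - A @ coef
        rss = dict(zip(_COORDS, (resid**2).sum(axis=0)))
        matrix, offset = coef[:3].T, coef[3]
        slope = {c: float(matrix[i, i]) for i, c in enumerate(_COORDS)}
        intercept = {c: float(offset[i]) for i, c in enumerate(_COORDS)}
        return CorrectionModel(
            slope=slope, intercept=intercept, rss={k: float(v) for k, v in rss.items()},
            matrix=matrix, offset=offset,
        )
    achrom = checker.subset("achromatic")
    chrom = checker.subset("chromatic")
    slope, intercept, rss = {}, {}, {}
    for coord, patches in (("L", achrom), ("a", chrom), ("b", chrom)):
        i = _COORDS.index(coord)
        x = np.array([p.measured[i] for p in patches])
        y = np.array([p.reference[i] for p in patches])
        slope[coord], intercept[coord], rss[coord] = _affine_lsq(x, y)
    return CorrectionModel(slope=slope, intercept=intercept, rss=rss)


def apply_correction(
    lab: LabRaster, model: CorrectionModel, *, return_clip_count: bool = False
):
    """Apply the fitted maps per pixel; L' is clipped to [0, 100].

    a* and b* are left unclipped (they have no comparable physical bound).
    """
    if model.matrix is not None:
        stacked = lab.stack() @ model.matrix.T + model.offset
        L, a, b = stacked[..., 0], stacked[..., 1], stacked[..., 2]
    else:
        L = model.slope["L"] * lab.L + model.intercept["L"]
        a = model.slope["a"] * lab.a + model.intercept["a"]
        b = model.slope["b"] * lab.b + model.intercept["b"]
    clipped = np.clip(L, 0.0, 100.0)
    n_clipped = int((clipped != L).sum())
    out = LabRaster(L=clipped, a=np.asarray(a, float), b=np.asarray(b, float))
    if return_clip_count:
        return out, n_clipped
    return out
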