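"""The two-dimensional color histogram (TDCH) over (L*, a*).

The color distribution of the valid tongue area is summarized on a 4 x 4
lattice of half-open rectangles.  The default lattice uses the lower bounds
L* in {30, 35, 40, 45} with width 5 and a* in {6, 12, 18, 24} with width 6,
i.e. 16 disjoint bins covering [30, 50) x [6, 30).  Each bin's pixel count is
normalized by the number of valid tongue pixels, giving an area proportion.

Seven of the sixteen proportions are promoted to named variables V1..V7.
Low-a* variables (V1-V4) track the pale, coated part of the tongue surface;
high-a* variables (V5-V7) track the red tongue body, with V7 — the brightest,
reddest bin — marking intense red tissue.  The ratio VR = V7/V3 indexes the
red intensity of the tongue body.  The bin-to-variable assignment is
configurable; the default satisfies the ordering constraints above and is
flagged in output metadata as a configuration choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .colorspace import LabRaster
from .errors import AnalysisError, ConfigError
from .segmentation import TongueMask

__all__ = [
    "TDCHGrid",
    "VariableMapping",
    "TDCHResult",
    "build_grid",
    "compute_histogram",
    "extract_variables",
    "v_ratio",
    "DEFAULT_MAPPING",
]

V_NAMES = tuple(f"V{i}" for i in range(1, 8))


@dataclass(frozen=True)
class TDCHGrid:
    """Rectangular (L*, a*) bin lattice of half-open bins [lo, lo+width)."""

    L_lower: tuple[float, ...] = (30.0, 35.0, 40.0, 45.0)
    L_width: float = 5.0
    a_lower: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    a_width: float = 6.0

    def __post_init__(self) -> None:
        for name, lows, width in (
            ("L", self.L_lower, self.L_width),
            ("a", self.a_lower, self.a_width),
        ):
            if width <= 0:
                raise ConfigError(f"{name} bin width must be positive")
            lows_sorted = sorted(lows)
            if tuple(lows_sorted) != tuple(lows):
                raise ConfigError(f"{name} lower bounds must be increasing")
            for lo, hi in zip(lows_sorted, lows_sorted[1:]):
                if lo + width > hi:
                    raise ConfigError(
                        f"{name} bins [{lo}, {lo + width}) and [{hi}, ...) overlap"
                    )

    @property
    def bins(self) -> list[tuple[float, float]]:
        """All (L_lower, a_lower) pairs, row-major in L then a."""
        return [(Lo, ao) for Lo in self.L_lower for ao in self.a_lower]

    @property
    def n_bins(self) -> int:
        return len(self.L_lower) * len(self.a_lower)

    def bin_of(self, L: float, a: float) -> tuple[float, float] | None:
        """The (L_lower, a_lower) bin containing the point, or None."""
        iL = self._axis_index(np.asarray([L]), self.L_lower, self.L_width)[0]
        ia = self._axis_index(np.asarray([a]), self.a_lower, self.a_width)[0]
        if iL < 0 or ia < 0:
            return None
        return (self.L_lower[iL], self.a_lower[ia])

    @staticmethod
    def _axis_index(v: np.ndarray, lows: tuple[float, ...], width: float) -> np.ndarray:
        lows_arr = np.asarray(lows, dtype=float)
        idx = np.searchsorted(lows_arr, v, side="right") - 1
        idx_c = np.clip(idx, 0, len(lows_arr) - 1)
        inside = (idx >= 0) & (v < lows_arr[idx_c] + width)
        return np.where(inside, idx_c, -1)

    def assign(self, L: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized per-pixel axis indices; -1 marks out-of-lattice."""
        return (
            self._axis_index(np.asarray(L, float).ravel(), self.L_lower, self.L_width),
            self._axis_index(np.asarray(a, float).ravel(), self.a_lower, self.a_width),
        )


def build_grid(
    L_lower=(30.0, 35.0, 40.0, 45.0),
    L_width: float = 5.0,
    a_lower=(6.0, 12.0, 18.0, 24.0),
    a_width: float = 6.0,
) -> TDCHGrid:
    """Construct a bin lattice; raises :class:`ConfigError` on overlap."""
    return TDCHGrid(
        L_lower=tuple(float(x) for x in L_lower),
        L_width=float(L_width),
        a_lower=tuple(float(x) for x in a_lower),
        a_width=float(a_width),
    )


# Default assignment of histogram bins to the seven variables.  Fixed by the
# ordering constraints (V1-V4 low a*, V5-V7 high a*, V7 highest in both axes,
# V1 lowest L*, V3's a* below V5's and V7's); configurable because the exact
# published assignment is pictorial, not numeric.
DEFAULT_MAPPING: dict[str, tuple[float, float]] = {
    "V1": (30.0, 6.0),
    "V2": (35.0, 6.0),
    "V3": (35.0, 12.0),
    "V4": (40.0, 6.0),
    "V5": (35.0, 18.0),
    "V6": (40.0, 18.0),
    "V7": (45.0, 24.0),
}


@dataclass(frozen=True)
class VariableMapping:
    """Mapping from V1..V7 to one (L_lower, a_lower) grid bin each."""

    bins: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MAPPING)
    )

    def validate(self, grid: TDCHGrid) -> None:
        if set(self.bins) != set(V_NAMES):
            raise ConfigError(f"mapping must cover exactly {V_NAMES}")
        grid_bins = set(grid.bins)
        for name, b in self.bins.items():
            if tuple(b) not in grid_bins:
                raise ConfigError(f"{name}: bin {b} is not a grid bin")
        if len(set(map(tuple, self.bins.values()))) != 7:
            raise ConfigError("variables must map to 7 distinct bins")
        a_mid_low = grid.a_lower[len(grid.a_lower) // 2 - 1]  # e.g. 12
        a_mid_high = grid.a_lower[len(grid.a_lower) // 2]  # e.g. 18
        for name in ("V1", "V2", "V3", "V4"):
            if self.bins[name][1] > a_mid_low:
                raise ConfigError(
                    f"constraint violated: {name} must lie in the low-a* half "
                    f"(a* lower bound <= {a_mid_low})"
                )
        for name in ("V5", "V6", "V7"):
            if self.bins[name][1] < a_mid_high:
                raise ConfigError(
                    f"constraint violated: {name} must lie in the high-a* half "
                    f"(a* lower bound >= {a_mid_high})"
                )
        L7, a7 = self.bins["V7"]
        if any(self.bins[n][0] > L7 or self.bins[n][1] > a7 for n in V_NAMES):
            raise ConfigError(
                "constraint violated: V7's bin must have the maximal L* and a* "
                "lower bounds among the seven"
            )
        if any(self.bins[n][0] < self.bins["V1"][0] for n in V_NAMES):
            raise ConfigError(
                "constraint violated: V1's bin must have the minimal L* lower bound"
            )
        if not (self.bins["V3"][1] < self.bins["V5"][1] and self.bins["V3"][1] < a7):
            raise ConfigError(
                "constraint violated: V3's a* lower bound must be below V5's and V7's"
            )


@dataclass(frozen=True)
class TDCHResult:
    """Counts and normalized proportions on the (L*, a*) lattice."""

    grid: TDCHGrid
    counts: dict[tuple[float, float], int]
    denominator: int

    @property
    def proportions(self) -> dict[tuple[float, float], float]:
        return {b: c / self.denominator for b, c in self.counts.items()}

    @property
    def in_lattice_fraction(self) -> float:
        return sum(self.counts.values()) / self.denominator


def compute_histogram(
    lab: LabRaster,
    valid: TongueMask,
    grid: TDCHGrid | None = None,
    *,
    denominator: int | None = None,
) -> TDCHResult:
    """Count valid tongue pixels per (L*, a*) bin and normalize.

    Each pixel belongs to at most one half-open bin; pixels outside the
    lattice are left uncounted but still appear in the denominator, which
    defaults to the number of valid tongue pixels (the post-exclusion area —
    pass an explicit ``denominator`` to normalize by the pre-exclusion area).
    """
    grid = grid or TDCHGrid()
    if valid.mask.shape != lab.shape:
        raise AnalysisError("valid mask and Lab raster shapes differ")
    n_valid = valid.n_pixels
    if n_valid == 0:
        raise AnalysisError("empty valid mask: no tongue pixels to histogram")
    L = np.asarray(lab.L, float)[valid.mask]
    a = np.asarray(lab.a, float)[valid.mask]
    iL, ia = grid.assign(L, a)
    inside = (iL >= 0) & (ia >= 0)
    nL, na = len(grid.L_lower), len(grid.a_lower)
    flat = iL[inside] * na + ia[inside]
    table = np.bincount(flat, minlength=nL * na)
    counts = {
        (Lo, ao): int(table[i * na + j])
        for i, Lo in enumerate(grid.L_lower)
        for j, ao in enumerate(grid.a_lower)
    }
    return TDCHResult(
        grid=grid, counts=counts, denominator=denominator or n_valid
    )


def extract_variables(
    result: TDCHResult, mapping: VariableMapping | None = None
) -> dict[str, float]:
    """Read V1..V7 off the mapped bins' proportions."""
    mapping = mapping or VariableMapping()
    mapping.validate(result.grid)
    props = result.proportions
    return {name: props[tuple(b)] for name, b in sorted(mapping.bins.items())}


def v_ratio(v3: float, v7: float) -> float:
    """VR = V7/V3, the red-intensity index of the tongue body.

    Undefined (NaN, with a warning) when V3 = 0; downstream summaries must
    drop undefined ratios.
    """
    if v3 == 0:
        warnings.warn("VR undefined: V3 = 0", stacklevel=2)
        return math.nan
    return v7 / v3
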