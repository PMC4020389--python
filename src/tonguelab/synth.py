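"""Synthetic tongue images and cohort tables with exact ground truth.

No clinical tongue photographs ship with this package, so every stage is
exercised on phantoms that emulate the relevant physics of the real images:

* an elliptical pale-red tongue body whose pixel colors are drawn from a
  known mixture over the TDCH bins (so the recovered histogram has an exact
  reference);
* a coating patch of a distinct (paler, low-a*) color near the top of the
  body;
* specular highlights (L* > 85, the saliva-reflection artifact) and a dark
  root band (L* < 30) that the exclusion stage must remove;
* a 12-patch color checker strip, and a per-coordinate affine distortion of
  the whole Lab image standing in for device color error — the correction
  stage must invert it from the checker alone.

Colors are specified in Lab and rendered to 8-bit sRGB through the inverse
conversion, so recovering them through the pipeline is a true round trip
through the color-space code.  Jitter inside a bin is truncated 0.75 Lab
units away from the bin edges so that 8-bit quantization cannot flip a
pixel's bin; pipeline error against the known mixture is then purely
multinomial.

Cohort tables draw each variable from scaled Beta distributions (proportions
live in [0, 1] and the real variables are skewed); the default group
parameters place the group medians and spreads at clinically plausible values
with the characteristic effect directions — coating-area variables V2 and V4
higher, tongue-body variables V5 and V7 lower, in the sleep-disorder group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .colorspace import LabRaster, lab_to_srgb
from .errors import SpecError
from .segmentation import TongueMask
from .tdch import TDCHGrid

__all__ = [
    "TonguePhantomSpec",
    "PhantomImage",
    "CohortSpec",
    "generate_tongue_image",
    "generate_cohort",
    "dice_suite_specs",
    "checker_layout",
    "DEFAULT_CHECKER_REFERENCES",
    "DEFAULT_CHECKER_ROLES",
]

# Synthetic checker card: 6 neutral grays (achromatic, calibrate L*) and 6
# saturated primaries/secondaries (chromatic, calibrate a*/b*).  All in-gamut
# for sRGB, also after the default device distortion.
DEFAULT_CHECKER_REFERENCES: tuple[tuple[float, float, float], ...] = (
    (20.0, 0.0, 0.0),
    (35.0, 0.0, 0.0),
    (50.0, 0.0, 0.0),
    (65.0, 0.0, 0.0),
    (80.0, 0.0, 0.0),
    (95.0, 0.0, 0.0),
    (45.0, 45.0, 25.0),   # red
    (65.0, 25.0, 50.0),   # orange
    (85.0, -5.0, 70.0),   # yellow
    (55.0, -45.0, 35.0),  # green
    (35.0, 15.0, -45.0),  # blue
    (50.0, 50.0, -25.0),  # magenta
)
DEFAULT_CHECKER_ROLES: tuple[str, ...] = ("achromatic",) * 6 + ("chromatic",) * 6

# Default body color mixture over (L* lower, a* lower) bins: most mass in the
# mid-lightness, mid-redness bins, a pale-coating tail at low a*.
DEFAULT_BODY_MIXTURE: dict[tuple[float, float], float] = {
    (30.0, 6.0): 0.04,
    (35.0, 6.0): 0.05,
    (40.0, 6.0): 0.08,
    (35.0, 12.0): 0.15,
    (40.0, 12.0): 0.20,
    (35.0, 18.0): 0.12,
    (40.0, 18.0): 0.25,
    (45.0, 18.0): 0.08,
    (45.0, 24.0): 0.03,
}


@dataclass(frozen=True)
class TonguePhantomSpec:
    """Geometry, colors and artifacts of one synthetic tongue image."""

    shape: tuple[int, int] = (200, 224)
    center: tuple[float, float] = (88.0, 112.0)
    semi_axes: tuple[float, float] = (62.0, 78.0)  # (row, col) semi-axes
    rotation_deg: float = 0.0
    body_mixture: dict[tuple[float, float], float] = field(
        default_factory=lambda: dict(DEFAULT_BODY_MIXTURE)
    )
    jitter_sigma: float = 1.0
    bin_margin: float = 0.75  # keep-out distance from bin edges, Lab units
    body_b: float = 14.0
    coating_fraction: float = 0.22  # coating patch semi-axes as a fraction
    coating_bin: tuple[float, float] | None = (40.0, 6.0)
    specular_count: int = 3
    specular_radius: float = 4.0
    specular_L: float = 92.0
    root_band_fraction: float = 0.12
    root_band_lab: tuple[float, float, float] = (22.0, 10.0, 8.0)
    background_lab: tuple[float, float, float] = (10.0, 0.0, 0.0)
    checker: bool = True
    checker_patch: tuple[int, int] = (12, 14)  # (height, width) per patch
    checker_gap: int = 3
    # device distortion: measured = slope * true + intercept, per coordinate
    distortion_slope: tuple[float, float, float] = (0.92, 0.95, 0.90)
    distortion_intercept: tuple[float, float, float] = (3.0, 1.0, -1.5)
    grid: TDCHGrid = field(default_factory=TDCHGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.body_mixture.values())
        if total > 1.0 + 1e-9:
            raise SpecError(f"body mixture proportions sum to {total} > 1")
        grid_bins = set(self.grid.bins)
        for b in self.body_mixture:
            if tuple(b) not in grid_bins:
                raise SpecError(f"body mixture bin {b} is not a grid bin")
        if self.coating_bin is not None and tuple(self.coating_bin) not in grid_bins:
            raise SpecError(f"coating bin {self.coating_bin} is not a grid bin")
        h, w = self.shape
        r0, c0 = self.center
        ar, ac = self.semi_axes
        if not (0 < r0 < h and 0 < c0 < w):
            raise SpecError("ellipse center outside image")
        if r0 - ar < 0 or r0 + ar > h or c0 - ac < 0 or c0 + ac > w:
            raise SpecError("ellipse does not fit inside the image")


@dataclass(frozen=True)
class PhantomImage:
    """A rendered phantom plus its exact ground truth."""

    rgb: np.ndarray
    lab_true: LabRaster  # scene Lab before device distortion
    tongue_mask: TongueMask
    artifact_mask: np.ndarray  # speculars + root band (to be excluded)
    true_counts: dict[tuple[float, float], int]  # per-bin, over valid pixels
    checker_regions: list[tuple[int, int, int, int]]
    checker_references: tuple[tuple[float, float, float], ...]
    checker_roles: tuple[str, ...]
    spec: TonguePhantomSpec

    @property
    def valid_mask(self) -> np.ndarray:
        return self.tongue_mask.mask & ~self.artifact_mask

    @property
    def true_proportions(self) -> dict[tuple[float, float], float]:
        n = int(self.valid_mask.sum())
        return {b: c / n for b, c in self.true_counts.items()}


def checker_layout(spec: TonguePhantomSpec) -> list[tuple[int, int, int, int]]:
    """Patch rectangles (row0, col0, height, width) of the checker strip.

    The 12 patches sit in one row along the bottom edge, achromatic six on
    the left; deterministic given the spec, so a pipeline configuration can
    be built without rendering the image.
    """
    h, w = spec.shape
    ph, pw = spec.checker_patch
    gap = spec.checker_gap
    total_w = 12 * pw + 11 * gap
    if total_w > w - 4 or ph + 4 > h:
        raise SpecError("checker strip does not fit inside the image")
    r0 = h - ph - 2
    c0 = (w - total_w) // 2
    return [(r0, c0 + i * (pw + gap), ph, pw) for i in range(12)]


def _ellipse_mask(
    shape, center, semi_axes, rotation_deg: float
) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = rows - center[0], cols - center[1]
    t = np.deg2rad(rotation_deg)
    u = dr * np.cos(t) + dc * np.sin(t)
    v = -dr * np.sin(t) + dc * np.cos(t)
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _truncated_jitter(rng, n: int, lo: float, hi: float, center: float, sigma: float):
    """Gaussian jitter around center, rejected outside [lo, hi]."""
    if hi <= lo:
        return np.full(n, center)
    out = center + sigma * rng.standard_normal(n)
    bad = (out < lo) | (out > hi)
    for _ in range(64):
        if not bad.any():
            break
        out[bad] = center + sigma * rng.standard_normal(int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def generate_tongue_image(spec: TonguePhantomSpec) -> PhantomImage:
    """Render one phantom; all returned truths are exact by construction."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    grid = spec.grid
    lab = np.empty((h, w, 3))
    lab[..., 0], lab[..., 1], lab[..., 2] = spec.background_lab

    tongue = _ellipse_mask(spec.shape, spec.center, spec.semi_axes, spec.rotation_deg)
    t_rows, t_cols = np.nonzero(tongue)
    n_body = len(t_rows)

    # --- body: per-pixel bin assignment from the mixture -------------------
    bins = list(spec.body_mixture)
    probs = np.array([spec.body_mixture[b] for b in bins])
    probs = probs / probs.sum()
    assignment = rng.choice(len(bins), size=n_body, p=probs)
    bin_index = np.full((h, w), -1, dtype=int)
    bin_index[t_rows, t_cols] = assignment
    for k, (Lo, ao) in enumerate(bins):
        sel = assignment == k
        n_k = int(sel.sum())
        if n_k == 0:
            continue
        m = spec.bin_margin
        Lvals = _truncated_jitter(
            rng, n_k, Lo + m, Lo + grid.L_width - m, Lo + grid.L_width / 2, spec.jitter_sigma
        )
        avals = _truncated_jitter(
            rng, n_k, ao + m, ao + grid.a_width - m, ao + grid.a_width / 2, spec.jitter_sigma
        )
        bvals = spec.body_b + spec.jitter_sigma * rng.standard_normal(n_k)
        rr, cc = t_rows[sel], t_cols[sel]
        lab[rr, cc, 0], lab[rr, cc, 1], lab[rr, cc, 2] = Lvals, avals, bvals

    # --- coating patch ------------------------------------------------------
    if spec.coating_bin is not None and spec.coating_fraction > 0:
        ar, ac = spec.semi_axes
        ccenter = (spec.center[0] - 0.45 * ar, spec.center[1])
        coating = _ellipse_mask(
            spec.shape, ccenter,
            (spec.coating_fraction * ar, spec.coating_fraction * ac * 1.6),
            spec.rotation_deg,
        ) & tongue
        k_rows, k_cols = np.nonzero(coating)
        n_k = len(k_rows)
        if n_k:
            Lo, ao = spec.coating_bin
            m = spec.bin_margin
            lab[k_rows, k_cols, 0] = _truncated_jitter(
                rng, n_k, Lo + m, Lo + grid.L_width - m, Lo + grid.L_width / 2,
                spec.jitter_sigma,
            )
            lab[k_rows, k_cols, 1] = _truncated_jitter(
                rng, n_k, ao + m, ao + grid.a_width - m, ao + grid.a_width / 2,
                spec.jitter_sigma,
            )
            lab[k_rows, k_cols, 2] = spec.body_b - 4.0 + spec.jitter_sigma * rng.standard_normal(n_k)
            bin_index[k_rows, k_cols] = len(bins)
            bins = bins + [tuple(spec.coating_bin)]

    # --- dark root band (top of the ellipse) --------------------------------
    artifact = np.zeros((h, w), dtype=bool)
    if spec.root_band_fraction > 0:
        row_min = t_rows.min()
        row_cut = row_min + spec.root_band_fraction * (t_rows.max() - row_min)
        band = tongue & (np.arange(h)[:, None] <= row_cut)
        lab[band] = spec.root_band_lab
        artifact |= band

    # --- specular spots ------------------------------------------------------
    for _ in range(spec.specular_count):
        # keep spots well inside the body, away from the root band
        theta = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.1, 0.55)
        t = np.deg2rad(spec.rotation_deg)
        u = rho * spec.semi_axes[0] * np.sin(theta)
        v = rho * spec.semi_axes[1] * np.cos(theta)
        sr = spec.center[0] + u * np.cos(t) - v * np.sin(t)
        sc = spec.center[1] + u * np.sin(t) + v * np.cos(t)
        spot = _ellipse_mask(
            spec.shape, (sr, sc), (spec.specular_radius, spec.specular_radius), 0.0
        ) & tongue
        lab[spot] = (spec.specular_L, 0.0, 0.0)
        artifact |= spot

    # --- checker strip -------------------------------------------------------
    regions: list[tuple[int, int, int, int]] = []
    if spec.checker:
        regions = checker_layout(spec)
        for (r0, c, ph, pw), ref in zip(regions, DEFAULT_CHECKER_REFERENCES):
            lab[r0 : r0 + ph, c : c + pw] = ref

    lab_true = LabRaster.from_stack(lab)

    # --- device distortion + rendering --------------------------------------
    sl, si = spec.distortion_slope, spec.distortion_intercept
    measured = np.stack(
        [lab[..., i] * sl[i] + si[i] for i in range(3)], axis=-1
    )
    rgb, n_clipped = lab_to_srgb(LabRaster.from_stack(measured), return_clip_count=True)
    if n_clipped > 0:
        raise SpecError(
            f"{n_clipped} pixels fell outside the sRGB gamut; "
            "soften the body/checker colors or the distortion"
        )

    valid = tongue & ~artifact
    counts: dict[tuple[float, float], int] = {b: 0 for b in grid.bins}
    vb = bin_index[valid]
    for k, b in enumerate(bins):
        counts[tuple(b)] = counts.get(tuple(b), 0) + int((vb == k).sum())
    return PhantomImage(
        rgb=rgb,
        lab_true=lab_true,
        tongue_mask=TongueMask(mask=tongue, provenance="auto"),
        artifact_mask=artifact,
        true_counts=counts,
        checker_regions=regions,
        checker_references=DEFAULT_CHECKER_REFERENCES,
        checker_roles=DEFAULT_CHECKER_ROLES,
        spec=spec,
    )


def dice_suite_specs(seed: int = 0) -> list[TonguePhantomSpec]:
    """Twenty ellipse variants: axis ratios 1.2–2.0 crossed with rotations 0–30 deg."""
    specs = []
    ratios = np.linspace(1.2, 2.0, 5)
    rotations = np.linspace(0.0, 30.0, 4)
    for i, ratio in enumerate(ratios):
        for j, rot in enumerate(rotations):
            ac = 72.0
            ar = ac / ratio
            specs.append(
                TonguePhantomSpec(
                    semi_axes=(float(ar), float(ac)),
                    rotation_deg=float(rot),
                    seed=seed + 13 * i + j,
                )
            )
    return specs


# ---------------------------------------------------------------------------
# cohort generation


_BETA_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def _beta_params(median: float, iqr: float) -> tuple[float, float]:
    """Beta(a, b) whose median and interquartile range match the targets.

    Nested root finds: for a trial concentration kappa the mean parameter is
    solved so the Beta median hits the target; kappa is then solved so the
    IQR matches (IQR is monotone decreasing in kappa).  Cached: the same
    group parameters are reused across subjects and replicates.
    """
    from scipy.optimize import brentq

    key = (median, iqr)
    if key in _BETA_CACHE:
        return _BETA_CACHE[key]

    def mean_for(kappa: float) -> float:
        def med_err(m: float) -> float:
            return sps.beta.ppf(0.5, m * kappa, (1 - m) * kappa) - median

        return brentq(med_err, 1e-4, 1 - 1e-4, xtol=1e-12)

    def iqr_err(kappa: float) -> float:
        m = mean_for(kappa)
        a, b = m * kappa, (1 - m) * kappa
        q1, q3 = sps.beta.ppf([0.25, 0.75], a, b)
        return (q3 - q1) - iqr

    kappa = brentq(iqr_err, 1.0, 5000.0, xtol=1e-9)
    m = mean_for(kappa)
    _BETA_CACHE[key] = (m * kappa, (1 - m) * kappa)
    return _BETA_CACHE[key]


# (location, IQR) per variable and condition.  Locations and spreads are
# plausible tongue-area proportions; the sleep-disorder condition raises the
# coating variables V2, V4 and lowers the tongue-body variables V5, V7.
DEFAULT_NORMAL_PARAMS: dict[str, tuple[float, float]] = {
    "V1": (0.048, 0.033),
    "V2": (0.042, 0.047),
    "V3": (0.130, 0.094),
    "V4": (0.080, 0.097),
    "V5": (0.130, 0.104),
    "V6": (0.211, 0.088),
    "V7": (0.082, 0.122),
}
DEFAULT_SLEEP_DISORDER_PARAMS: dict[str, tuple[float, float]] = {
    "V1": (0.048, 0.038),
    "V2": (0.062, 0.092),
    "V3": (0.127, 0.103),
    "V4": (0.136, 0.168),
    "V5": (0.075, 0.088),
    "V6": (0.185, 0.122),
    "V7": (0.038, 0.116),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions for a synthetic subject cohort."""

    n_normal: int = 402
    n_sleep_disorder: int = 52
    normal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NORMAL_PARAMS)
    )
    sleep_disorder_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SLEEP_DISORDER_PARAMS)
    )
    paired: bool = False
    n_paired: int = 18
    correlation: float = 0.7  # within-subject copula correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal <= 0 or self.n_sleep_disorder <= 0 or self.n_paired <= 0:
            raise SpecError("cohort sizes must be positive")
        for params in (self.normal_params, self.sleep_disorder_params):
            for var, (loc, scale) in params.items():
                if not (0 < loc < 1):
                    raise SpecError(f"{var}: location must lie in (0, 1)")
                if scale <= 0:
                    raise SpecError(f"{var}: scale must be positive")


def _draw_group(rng, n: int, params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    data = {}
    for var, (loc, iqr) in params.items():
        a, b = _beta_params(loc, iqr)
        data[var] = rng.beta(a, b, size=n)
    return pd.DataFrame(data)


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a cohort table: subject_id, visit, group, V1..V7, VR.

    Independent subjects per group; in paired mode each subject appears with
    a 'first' visit drawn from the normal condition and a 'second' visit from
    the sleep-disorder condition, coupled through a Gaussian copula so that
    within-subject values are correlated.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    frames = []
    if spec.paired:
        n = spec.n_paired
        rho = spec.correlation
        first = {}
        second = {}
        for var in spec.normal_params:
            a1, b1 = _beta_params(*spec.normal_params[var])
            a2, b2 = _beta_params(*spec.sleep_disorder_params[var])
            z1 = rng.standard_normal(n)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            first[var] = sps.beta.ppf(sps.norm.cdf(z1), a1, b1)
            second[var] = sps.beta.ppf(sps.norm.cdf(z2), a2, b2)
        for visit, group, data in (
            ("first", "normal", first),
            ("second", "sleep_disorder", second),
        ):
            df = pd.DataFrame(data)
            df.insert(0, "group", group)
            df.insert(0, "visit", visit)
            df.insert(0, "subject_id", [f"P{i + 1:04d}" for i in range(n)])
            frames.append(df)
    else:
        for group, n, params in (
            ("normal", spec.n_normal, spec.normal_params),
            ("sleep_disorder", spec.n_sleep_disorder, spec.sleep_disorder_params),
        ):
            df = _draw_group(rng, n, params)
            df.insert(0, "group", group)
            df.insert(0, "visit", "first")
            prefix = "N" if group == "normal" else "D"
            df.insert(0, "subject_id", [f"{prefix}{i + 1:04d}" for i in range(n)])
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["VR"] = np.where(out["V3"] > 0, out["V7"] / out["V3"], np.nan)
    return out
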