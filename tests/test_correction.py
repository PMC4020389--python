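"""Checker sampling and least-squares color correction."""

import numpy as np
import pytest

from tonguelab.colorspace import LabRaster
from tonguelab.correction import (
    CheckerPatch,
    CheckerSet,
    CorrectionModel,
    apply_correction,
    fit_correction,
    sample_checker,
)
from tonguelab.errors import FitError, FormatError
from tonguelab.synth import DEFAULT_CHECKER_REFERENCES, DEFAULT_CHECKER_ROLES

REFS = list(DEFAULT_CHECKER_REFERENCES)
ROLES = list(DEFAULT_CHECKER_ROLES)


def checker_from_pairs(measured, references=REFS, roles=ROLES) -> CheckerSet:
    return CheckerSet(
        patches=tuple(
            CheckerPatch(patch_id=f"P{i:02d}", role=r, reference=tuple(ref), measured=tuple(m))
            for i, (r, ref, m) in enumerate(zip(roles, references, measured))
        )
    )


def grid_image(values, patch=(4, 4)):
    """Lay 12 constant Lab patches in a row with 1-px gaps on a zero image."""
    h = patch[0] + 2
    w = 12 * (patch[1] + 1) + 1
    lab = np.zeros((h, w, 3))
    regions = []
    for i, v in enumerate(values):
        c0 = 1 + i * (patch[1] + 1)
        lab[1 : 1 + patch[0], c0 : c0 + patch[1]] = v
        regions.append((1, c0, patch[0], patch[1]))
    return LabRaster.from_stack(lab), regions


class TestSampleChecker:
    def test_constant_region_measured_exactly(self):
        lab, regions = grid_image(REFS)
        checker = sample_checker(lab, regions, REFS, ROLES)
        for p, ref in zip(checker.patches, REFS):
            assert p.measured == pytest.approx(ref, abs=1e-12)

    def test_half_and_half_region_measures_midpoint(self):
        lab, regions = grid_image(REFS)
        r0, c0, ph, pw = regions[0]
        arr = lab.stack()
        arr[r0 : r0 + ph // 2, c0 : c0 + pw] = (10.0, 0.0, 0.0)
        arr[r0 + ph // 2 : r0 + ph, c0 : c0 + pw] = (30.0, 0.0, 0.0)
        checker = sample_checker(LabRaster.from_stack(arr), regions, REFS, ROLES)
        assert checker.patches[0].measured[0] == pytest.approx(20.0)

    def test_noisy_region_mean_within_sampling_error(self, rng):
        lab, regions = grid_image(REFS, patch=(20, 20))
        arr = lab.stack()
        arr += rng.normal(0.0, 1.0, arr.shape)
        checker = sample_checker(LabRaster.from_stack(arr), regions, REFS, ROLES)
        bound = 3.0 / np.sqrt(400)
        for p, ref in zip(checker.patches, REFS):
            assert abs(p.measured[0] - ref[0]) < bound

    def test_bad_regions_rejected(self):
        lab, regions = grid_image(REFS)
        outside = [regions[0][:1] + (10_000,) + regions[0][2:]] + regions[1:]
        with pytest.raises(FormatError):
            sample_checker(lab, outside, REFS, ROLES)
        tiny = [(1, 1, 1, 3)] + regions[1:]
        with pytest.raises(FormatError):
            sample_checker(lab, tiny, REFS, ROLES)
        overlapping = [regions[0], regions[0]] + regions[2:]
        with pytest.raises(FormatError):
            sample_checker(lab, overlapping, REFS, ROLES)

    def test_checker_requires_six_of_each_role(self):
        with pytest.raises(FormatError):
            checker_from_pairs(REFS, roles=["achromatic"] * 12)


def brute_force_affine(x, y):
    """Explicit 2x2 normal-equations solve, independent of lstsq."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    A = np.array([[np.sum(x * x), np.sum(x)], [np.sum(x), n]])
    rhs = np.array([np.sum(x * y), np.sum(y)])
    slope, intercept = np.linalg.solve(A, rhs)
    return slope, intercept


class TestFitCorrection:
    def test_perfect_checker_gives_identity(self):
        model = fit_correction(checker_from_pairs(REFS))
        for c in "Lab":
            assert model.slope[c] == pytest.approx(1.0, abs=1e-12)
            assert model.intercept[c] == pytest.approx(0.0, abs=1e-9)
            assert model.rss[c] == pytest.approx(0.0, abs=1e-18)

    def test_recovers_known_affine_distortion(self):
        measured = [((L - 3.0) / 0.9, a, b) for (L, a, b) in REFS]
        model = fit_correction(checker_from_pairs(measured))
        assert model.slope["L"] == pytest.approx(0.9, abs=1e-9)
        assert model.intercept["L"] == pytest.approx(3.0, abs=1e-9)

    def test_matches_brute_force_normal_equations(self, rng):
        measured = [tuple(np.array(ref) + rng.normal(0, 2, 3)) for ref in REFS]
        model = fit_correction(checker_from_pairs(measured))
        achrom = [(m, r) for m, r, role in zip(measured, REFS, ROLES) if role == "achromatic"]
        slope, intercept = brute_force_affine(
            [m[0] for m, _ in achrom], [r[0] for _, r in achrom]
        )
        assert model.slope["L"] == pytest.approx(slope, abs=1e-9)
        assert model.intercept["L"] == pytest.approx(intercept, abs=1e-9)
        chrom = [(m, r) for m, r, role in zip(measured, REFS, ROLES) if role == "chromatic"]
        for coord, i in (("a", 1), ("b", 2)):
            slope, intercept = brute_force_affine(
                [m[i] for m, _ in chrom], [r[i] for _, r in chrom]
            )
            assert model.slope[coord] == pytest.approx(slope, abs=1e-9)
            assert model.intercept[coord] == pytest.approx(intercept, abs=1e-9)

    def test_least_squares_optimality_under_perturbation(self, rng):
        measured = [tuple(np.array(ref) + rng.normal(0, 2, 3)) for ref in REFS]
        checker = checker_from_pairs(measured)
        model = fit_correction(checker)
        achrom = checker.subset("achromatic")
        x = np.array([p.measured[0] for p in achrom])
        y = np.array([p.reference[0] for p in achrom])

        def rss(slope, intercept):
            return np.sum((y - slope * x - intercept) ** 2)

        best = rss(model.slope["L"], model.intercept["L"])
        for ds in (-1e-3, 1e-3):
            assert rss(model.slope["L"] + ds, model.intercept["L"]) >= best
            assert rss(model.slope["L"], model.intercept["L"] + ds) >= best

    def test_degenerate_design_raises(self):
        measured = [(50.0, 0.0, 0.0)] * 12
        with pytest.raises(FitError):
            fit_correction(checker_from_pairs(measured))

    def test_cross_channel_mode_fits_exactly_on_linear_data(self, rng):
        M = rng.normal(0, 1, (3, 3)) * 0.1 + np.eye(3)
        off = np.array([2.0, -1.0, 0.5])
        measured = [tuple(np.linalg.solve(M, np.array(r) - off)) for r in REFS]
        model = fit_correction(checker_from_pairs(measured), cross_channel=True)
        assert np.abs(model.matrix - M).max() < 1e-8
        assert np.abs(model.offset - off).max() < 1e-7


class TestApplyCorrection:
    def test_identity_model_is_a_no_op(self, rng):
        lab = LabRaster.from_stack(rng.uniform(20, 60, (5, 5, 3)))
        out = apply_correction(lab, CorrectionModel.identity())
        assert np.abs(out.stack() - lab.stack()).max() == 0

    def test_affine_arithmetic_and_L_clipping(self):
        lab = LabRaster(
            L=np.array([[40.0, 60.0]]), a=np.zeros((1, 2)), b=np.zeros((1, 2))
        )
        model = CorrectionModel(
            slope={"L": 2.0, "a": 1.0, "b": 1.0},
            intercept={"L": 0.0, "a": 0.0, "b": 0.0},
            rss={"L": 0.0, "a": 0.0, "b": 0.0},
        )
        out, n_clipped = apply_correction(lab, model, return_clip_count=True)
        assert out.L[0, 0] == 80.0
        assert out.L[0, 1] == 100.0 and n_clipped == 1

    def test_end_to_end_recovery_on_distorted_phantom(self, default_phantom):
        """Fitting on the rendered (distorted) checker must undo the distortion."""
        from tonguelab.colorspace import srgb_to_lab

        lab = srgb_to_lab(default_phantom.rgb)
        checker = sample_checker(
            lab,
            default_phantom.checker_regions,
            list(default_phantom.checker_references),
            list(default_phantom.checker_roles),
        )
        model = fit_correction(checker)
        corrected = apply_correction(lab, model)
        for (r0, c0, ph, pw), ref in zip(
            default_phantom.checker_regions, default_phantom.checker_references
        ):
            got = (
                corrected.L[r0 : r0 + ph, c0 : c0 + pw].mean(),
                corrected.a[r0 : r0 + ph, c0 : c0 + pw].mean(),
                corrected.b[r0 : r0 + ph, c0 : c0 + pw].mean(),
            )
            assert got == pytest.approx(ref, abs=0.6)  # 8-bit quantization floor
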