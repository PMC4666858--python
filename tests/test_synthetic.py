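"""Simulator ground truth: exact construction, noise statistics, geometry,
determinism, and cohort generation."""

import numpy as np
import pytest

from fiberratio.group_stats import RGroup, pooled_two_sample_test
from fiberratio.ratiometry import fiber_R
from fiberratio.soi import select_sois
from fiberratio.synthetic import (
    AcquisitionParams,
    FiberGeometry,
    GroupSpec,
    generate_cohort,
    generate_fiber_stack,
)


class TestNoiseFreeConstruction:
    @pytest.mark.parametrize("rho", [1.0, 2.0])
    def test_mask_ratio_exact_without_noise_and_blur(self, geometry, acq_fast, rho):
        stack, truth = generate_fiber_stack(
            geometry, acq_fast, rho, seed=0, blur=False, noise=False
        )
        disl = truth.mask_mean(stack, "dislocation")
        wall = truth.mask_mean(stack, "normal_wall")
        assert disl / wall == pytest.approx(rho, rel=0, abs=0)

    def test_compartment_densities(self, geometry, acq_fast):
        stack, truth = generate_fiber_stack(
            geometry, acq_fast, 2.0, seed=0, blur=False, noise=False
        )
        ps = acq_fast.photon_scale
        assert truth.mask_mean(stack, "lumen") == 0.0
        assert truth.mask_mean(stack, "normal_wall") == ps
        assert truth.mask_mean(stack, "surface_layer") == pytest.approx(
            acq_fast.surface_enrichment_factor * ps
        )
        assert truth.mask_mean(stack, "bulk_solution") == pytest.approx(
            acq_fast.background_level * ps
        )

    def test_photon_scale_conservation(self, geometry, acq_fast):
        """Scaling photon_scale by c scales noise-free intensities by c and
        leaves every mask-based ratio unchanged."""
        c = 3.7
        scaled = AcquisitionParams(
            pixel_size_nm=acq_fast.pixel_size_nm,
            photon_scale=acq_fast.photon_scale * c,
        )
        s1, t1 = generate_fiber_stack(FiberGeometry(), acq_fast, 2.0, seed=0,
                                      noise=False)
        s2, t2 = generate_fiber_stack(FiberGeometry(), scaled, 2.0, seed=0,
                                      noise=False)
        np.testing.assert_allclose(s2.intensities, c * s1.intensities,
                                   rtol=1e-12)
        r1 = t1.mask_mean(s1, "dislocation") / t1.mask_mean(s1, "normal_wall")
        r2 = t2.mask_mean(s2, "dislocation") / t2.mask_mean(s2, "normal_wall")
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestNoisyRecoveryAgainstMaskOracle:
    def test_mask_ratio_unbiased_over_replicates(self, geometry, acq_fast):
        """Monte-Carlo: mean of mask-based ratios within 3 SE of rho = 2.

        The oracle is direct voxel-mask averaging, independent of the
        ROI/SOI pipeline; blur is off so the masks delimit pure
        compartments.
        """
        n = 20
        ratios = []
        for i in range(n):
            stack, truth = generate_fiber_stack(
                geometry, acq_fast, 2.0, seed=1000 + i, blur=False
            )
            ratios.append(
                truth.mask_mean(stack, "dislocation")
                / truth.mask_mean(stack, "normal_wall")
            )
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(n)
        assert abs(ratios.mean() - 2.0) < 3 * max(se, 1e-12)


class TestGeometry:
    def test_lumen_present_only_near_equator(self, geometry, acq_fast):
        _, truth = generate_fiber_stack(geometry, acq_fast, 1.5, seed=0)
        lumen_per_slice = truth.mask("lumen").sum(axis=(1, 2))
        assert lumen_per_slice[0] == 0 and lumen_per_slice[-1] == 0
        zc = acq_fast.scan_depth_um / 2.0
        for k in range(acq_fast.n_slices):
            depth = k * acq_fast.slice_spacing_um
            inside = abs(depth - zc) < geometry.lumen_diameter / 2.0
            assert (lumen_per_slice[k] > 0) == inside

    def test_masks_exclusive_exhaustive(self, geometry, acq_fast):
        _, truth = generate_fiber_stack(geometry, acq_fast, 1.5, seed=0)
        names = ["background", "bulk_solution", "normal_wall", "dislocation",
                 "lumen", "surface_layer"]
        total = sum(truth.mask(n).sum() for n in names)
        assert total == truth.labels.size

    def test_fiber_must_fit_field_of_view(self, acq_fast):
        big = FiberGeometry(fiber_diameter=50.0, lumen_diameter=8.0)
        with pytest.raises(ValueError, match="does not fit"):
            generate_fiber_stack(big, acq_fast, 1.0, seed=0)

    def test_nonpositive_rho_rejected(self, geometry, acq_fast):
        with pytest.raises(ValueError, match="rho_true"):
            generate_fiber_stack(geometry, acq_fast, 0.0, seed=0)

    def test_coverage_below_half_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            FiberGeometry(dislocation_bands=((12.0, 4.0, 0.3),))


class TestDeterminism:
    def test_identical_seed_bit_identical(self, geometry, acq_coarse):
        s1, _ = generate_fiber_stack(geometry, acq_coarse, 2.0, seed=42)
        s2, _ = generate_fiber_stack(geometry, acq_coarse, 2.0, seed=42)
        assert s1.intensities.tobytes() == s2.intensities.tobytes()

    def test_different_seeds_differ(self, geometry, acq_coarse):
        s1, _ = generate_fiber_stack(geometry, acq_coarse, 2.0, seed=42)
        s2, _ = generate_fiber_stack(geometry, acq_coarse, 2.0, seed=43)
        assert not np.array_equal(s1.intensities, s2.intensities)


class TestCohort:
    def test_cardinality_and_complete_roisets(self, acq_coarse):
        cohort = generate_cohort(
            [GroupSpec("EGV", 12, 2.0)], acq_coarse, seed=5
        )
        assert len(cohort) == 12
        for cube, truth in cohort:
            assert len(cube.rois.of_kind("normal_wall")) == 3
            assert len(cube.rois.of_kind("dislocation")) == 3
            assert len(cube.rois.of_kind("bulk")) == 3
            assert cube.rois.lumen is not None

    def test_same_master_seed_reproduces_cohort(self, acq_coarse):
        spec = [GroupSpec("a", 2, 2.0), GroupSpec("b", 2, 1.0, washed=True)]
        c1 = generate_cohort(spec, acq_coarse, seed=9)
        c2 = generate_cohort(spec, acq_coarse, seed=9)
        for (cube1, _), (cube2, _) in zip(c1, c2):
            assert cube1.fiber_id == cube2.fiber_id
            assert cube1.stack.intensities.tobytes() == \
                cube2.stack.intensities.tobytes()
            assert cube1.rois.rois == cube2.rois.rois

    def test_two_group_cohort_separates_downstream(self, acq_coarse):
        """Power check: rho 2.0 vs 1.0 at n = 12 fibers per group is
        declared significant (CI excludes 0) in >= 95 % of cohort
        replicates, using the package's own statistics stage."""
        n_reps = 100
        hits = 0
        for rep in range(n_reps):
            cohort = generate_cohort(
                [GroupSpec("hi", 12, 2.0), GroupSpec("lo", 12, 1.0)],
                acq_coarse,
                seed=20_000 + rep,
            )
            values = {"hi": [], "lo": []}
            for cube, _ in cohort:
                sois = select_sois(cube.stack, cube.rois)
                values[cube.enzyme].append(
                    fiber_R(cube.stack, cube.rois, sois).mean_R
                )
            test = pooled_two_sample_test(
                RGroup("hi", values["hi"]), RGroup("lo", values["lo"])
            )
            hits += test.significant
        assert hits >= 0.95 * n_reps
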