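"""Phantom patch simulation: noise scaling, object rendering, designs."""

import numpy as np
import pandas as pd
import pytest

from lcdbench.errors import (
    InvalidConditionError,
    InvalidDesignError,
    PlacementError,
)
from lcdbench.phantom_sim import (
    AcquisitionCondition,
    ImagePatch,
    NoiseModel,
    ObjectSpec,
    PatchGeometry,
    generate_test_set,
    generate_training_set,
    make_background,
    noise_sigma_for,
    render_case,
    render_object,
)

GEOM = PatchGeometry()


class TestNoiseSigma:
    @pytest.mark.parametrize(
        "mas,recon,expected",
        [
            (200.0, "FBP", 10.0),
            (26.0, "FBP", 10.0 * np.sqrt(200.0 / 26.0)),  # 27.735
            (200.0, "ADMIRE", 7.0),
            (50.0, "FBP", 20.0),
        ],
    )
    def test_quantum_scaling(self, mas, recon, expected):
        model = NoiseModel(sigma_ref=10.0, admire_factor=0.7)
        sigma = noise_sigma_for(AcquisitionCondition(mas=mas, recon=recon), model)
        assert sigma == pytest.approx(expected, rel=1e-9)

    def test_invalid_condition(self):
        with pytest.raises(InvalidConditionError):
            AcquisitionCondition(mas=0.0)
        with pytest.raises(InvalidConditionError):
            AcquisitionCondition(mas=100.0, recon="IR40")
        with pytest.raises(InvalidConditionError):
            NoiseModel(admire_factor=1.5)


class TestBackground:
    def test_zero_noise_is_constant(self):
        patch = make_background(64, 70.0, 0.0, seed=3)
        assert np.all(patch.pixels == 70.0)

    def test_seeded_determinism(self):
        a = make_background(64, 70.0, 10.0, seed=1)
        b = make_background(64, 70.0, 10.0, seed=1)
        assert np.array_equal(a.pixels, b.pixels)
        c = make_background(64, 70.0, 10.0, seed=2)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_sample_moments(self):
        patch = make_background(256, 70.0, 10.0, seed=7)
        assert patch.pixels.mean() == pytest.approx(70.0, abs=0.5)
        assert patch.pixels.std() == pytest.approx(10.0, abs=0.5)

    def test_correlated_noise_keeps_sigma(self):
        patch = make_background(256, 70.0, 10.0, seed=9, corr_px=1.0)
        assert patch.pixels.std() == pytest.approx(10.0, abs=1.0)

    def test_too_small(self):
        with pytest.raises(InvalidDesignError):
            make_background(4, 70.0, 10.0, seed=0)


class TestRenderObject:
    def test_additive_interior_and_exterior(self):
        base = make_background(64, 70.0, 0.0, seed=0)
        spec = ObjectSpec(True, 9.0, 10.0, (25.0, 25.0))
        out = render_object(base, spec)
        # a pixel well inside the disk and one far outside
        cx_px = int(25.0 / GEOM.spacing_mm)
        assert out.pixels[cx_px, cx_px] == pytest.approx(80.0)
        assert out.pixels[5, 5] == pytest.approx(70.0)
        assert np.all(out.pixels >= 70.0)

    @pytest.mark.parametrize("diameter", [5.0, 9.0, 15.0])
    def test_analytic_disk_area(self, diameter):
        base = make_background(64, 70.0, 0.0, seed=0)
        spec = ObjectSpec(True, diameter, 10.0, (25.0, 25.0))
        out = render_object(base, spec)
        increment = float((out.pixels - 70.0).sum())
        analytic = 10.0 * np.pi * (diameter / 2) ** 2 / GEOM.spacing_mm**2
        assert increment == pytest.approx(analytic, rel=0.02)

    def test_out_of_bounds_placement(self):
        base = make_background(64, 70.0, 0.0, seed=0)
        spec = ObjectSpec(True, 9.0, 10.0, (2.0, 2.0))  # overlaps the corner
        with pytest.raises(PlacementError):
            render_object(base, spec)

    def test_original_patch_untouched(self):
        base = make_background(64, 70.0, 0.0, seed=0)
        render_object(base, ObjectSpec(True, 9.0, 10.0, (25.0, 25.0)))
        assert np.all(base.pixels == 70.0)


class TestTrainingSet:
    def test_exact_split_and_ranges(self):
        manifest, images = generate_training_set(n_images=1000, seed=5)
        assert len(manifest) == 1000
        assert manifest["present"].sum() == 500
        present = manifest[manifest["present"]]
        assert present["diameter_mm"].between(3.0, 20.0).all()
        assert present["contrast_hu"].between(5.0, 30.0).all()
        # every disk in bounds: center at least one radius from every edge
        radius = present["diameter_mm"] / 2
        for col in ("center_x_mm", "center_y_mm"):
            assert (present[col] >= radius - 1e-9).all()
            assert (present[col] <= GEOM.side_mm - radius + 1e-9).all()
        assert images.shape == (1000, 64, 64)

    def test_seeded_reproducibility(self):
        m1, i1 = generate_training_set(n_images=10, seed=3)
        m2, i2 = generate_training_set(n_images=10, seed=3)
        pd.testing.assert_frame_equal(m1, m2)
        assert np.array_equal(i1, i2)

    def test_odd_count_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_training_set(n_images=11, seed=0)


class TestTestSet:
    def test_minimal_grid(self):
        manifest, images = generate_test_set(
            per_cell_present=1,
            per_cell_absent=1,
            sizes_mm=(9.0,),
            doses=(200.0,),
            recons=("FBP",),
            seed=0,
        )
        assert len(manifest) == 2
        assert manifest["present"].sum() == 1

    def test_cell_structure(self, small_test_set):
        manifest, _ = small_test_set
        cells = manifest.groupby(["mas", "recon", "diameter_mm"])
        assert len(cells) == 16
        assert (cells.size() == 4).all()
        assert (cells["present"].sum() == 2).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidDesignError):
            generate_test_set(sizes_mm=(), seed=0)

    def test_geometry_invariant(self, small_test_set):
        manifest, _ = small_test_set
        present = manifest[manifest["present"]]
        radius = present["diameter_mm"] / 2
        for col in ("center_x_mm", "center_y_mm"):
            assert (present[col] >= radius - 1e-9).all()
            assert (present[col] <= GEOM.side_mm - radius + 1e-9).all()


class TestNoiseProperties:
    def _measured_sd(self, mas, recon, n=50):
        model = NoiseModel(sigma_ref=10.0)
        sds = []
        for i in range(n):
            patch = render_case(
                seed=1000 + i,
                condition=AcquisitionCondition(mas=mas, recon=recon),
                model=model,
                obj=ObjectSpec(present=False),
            )
            sds.append(patch.pixels.std())
        return float(np.mean(sds))

    def test_noise_increases_as_dose_drops(self):
        sds = [self._measured_sd(mas, "FBP") for mas in (200.0, 100.0, 50.0, 26.0)]
        assert all(a < b for a, b in zip(sds, sds[1:]))

    @pytest.mark.parametrize("mas", [200.0, 26.0])
    def test_admire_never_noisier(self, mas):
        assert self._measured_sd(mas, "ADMIRE") <= self._measured_sd(mas, "FBP")


def test_render_case_is_pure_function_of_row(small_test_set):
    manifest, images = small_test_set
    row = manifest[manifest["present"]].iloc[0]
    patch = render_case(
        seed=int(row["seed"]),
        condition=AcquisitionCondition(mas=row["mas"], recon=row["recon"]),
        model=NoiseModel(),
        obj=ObjectSpec(
            True, row["diameter_mm"], row["contrast_hu"],
            (row["center_x_mm"], row["center_y_mm"]),
        ),
    )
    idx = manifest.index[manifest["case_id"] == row["case_id"]][0]
    assert np.array_equal(patch.pixels, images[idx])


def test_image_patch_requires_square():
    with pytest.raises(ValueError):
        ImagePatch(pixels=np.zeros((4, 8)), spacing_mm=1.0)
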