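"""Rendering: background statistics, mask/record consistency, datasets."""

import numpy as np
import pytest
from shapely.geometry import LineString

from caulotype.config import OpticsConfig
from caulotype.geometry import arc_length, circular_arc, trim_polyline
from caulotype.render import load_image, load_truth, make_dataset, render
from caulotype.scenes import CellSpec, SceneSpec, build_scene

SMALL = OpticsConfig(frame_shape=(512, 512))


def test_empty_scene_mean_is_background(blank_frame, small_optics):
    image, truth = blank_frame
    opt = small_optics
    n = image.size
    noise_sd = np.sqrt(
        opt.photon_noise_scale**2 * opt.background_level + opt.read_noise_sd**2
    )
    assert abs(image.mean() - opt.background_level) <= 3 * noise_sd / np.sqrt(n) + 1.0
    assert truth.semantic_mask.max() == 0
    assert truth.records.empty


def _single_rod_scene(optics, length=3.0, width=0.8, curvature=0.0):
    centerline = circular_arc(length, curvature, n=64) + np.array([10.0, 10.0])
    cell = CellSpec(
        id=1, true_class="swarmer", centerline=centerline,
        width=width, curvature=curvature,
    )
    return SceneSpec(cells=[cell], optics=optics, seed=0, condition_preset="unit")


@pytest.mark.parametrize("pixel_size", [0.05, 0.065, 0.1])
def test_rod_mask_area_matches_capsule_oracle(pixel_size):
    """Semantic-mask area tracks the analytic capsule polygon within 5%
    across pixel sizes (area scales as 1/pixel_size^2)."""
    optics = OpticsConfig(pixel_size=pixel_size, frame_shape=(512, 512))
    scene = _single_rod_scene(optics)
    _, truth = render(scene)
    area_px = int((truth.semantic_mask == 1).sum())
    cl = scene.cells[0].centerline
    poly = LineString(trim_polyline(cl, 0.4)[:, ::-1]).buffer(0.4)
    assert area_px * pixel_size**2 == pytest.approx(poly.area, rel=0.05)


def test_default_field_of_view_is_133um():
    assert OpticsConfig().field_size_um == (pytest.approx(133.12), pytest.approx(133.12))


def test_render_is_deterministic():
    scene = build_scene("exponential", 10, SMALL, seed=21)
    img1, truth1 = render(scene)
    img2, truth2 = render(scene)
    assert np.array_equal(img1, img2)
    assert np.array_equal(truth1.semantic_mask, truth2.semantic_mask)


def test_instance_pixels_carry_semantic_labels():
    scene = build_scene("exponential", 15, SMALL, seed=2)
    _, truth = render(scene)
    assert (truth.semantic_mask[truth.cell_instance_mask > 0] == 1).all()
    assert (truth.semantic_mask[truth.stalk_instance_mask > 0] == 2).all()
    # every record id appears in exactly one instance mask
    body_ids = set(np.unique(truth.cell_instance_mask)) - {0}
    assert body_ids == set(truth.records["id"])


def test_truth_lengths_are_analytic():
    scene = build_scene("exponential", 10, SMALL, seed=2)
    _, truth = render(scene)
    for cell, (_, rec) in zip(scene.cells, truth.records.iterrows()):
        assert rec["length_um"] == pytest.approx(arc_length(cell.centerline), abs=1e-9)
        if cell.stalk is not None:
            assert rec["stalk_length_um"] == pytest.approx(
                arc_length(cell.stalk.polyline), abs=1e-9
            )


def test_overflow_is_clipped_with_logged_warning(caplog):
    optics = OpticsConfig(
        frame_shape=(128, 128), background_level=64000, cell_contrast=1500,
        halo_amplitude=3.0,
    )
    scene = _single_rod_scene(optics, length=2.0, width=0.7)
    import logging

    with caplog.at_level(logging.WARNING, logger="caulotype.render"):
        image, _ = render(scene)
    assert image.max() == 65535
    assert any("clipped" in r.message for r in caplog.records)


class TestMakeDataset:
    def test_72_image_protocol(self, tmp_path):
        """A 72-image training-style set yields 72 image/mask/record triples
        plus a manifest (tiny frames keep this fast)."""
        optics = OpticsConfig(frame_shape=(64, 64))
        manifest = make_dataset(
            tmp_path / "d", {"exponential": 40, "c_lim": 16, "p_lim": 16},
            n_cells=0, optics=optics, base_seed=5,
        )
        assert len(manifest) == 72
        for stem in manifest["stem"]:
            for suffix in ("", "_semantic", "_cells", "_stalks"):
                assert (tmp_path / "d" / f"{stem}{suffix}.tif").exists()
            assert (tmp_path / "d" / f"{stem}_records.csv").exists()
        assert (tmp_path / "d" / "manifest.csv").exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        optics = OpticsConfig(frame_shape=(128, 128))
        for sub in ("a", "b"):
            make_dataset(tmp_path / sub, {"exponential": 1}, n_cells=3,
                         optics=optics, base_seed=9)
        a = (tmp_path / "a" / "img_000.tif").read_bytes()
        b = (tmp_path / "b" / "img_000.tif").read_bytes()
        assert a == b

    def test_refuses_nonempty_dir_without_overwrite(self, tmp_path):
        out = tmp_path / "d"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            make_dataset(out, {"exponential": 1}, n_cells=0,
                         optics=OpticsConfig(frame_shape=(64, 64)))
        make_dataset(out, {"exponential": 1}, n_cells=0,
                     optics=OpticsConfig(frame_shape=(64, 64)), overwrite=True)

    def test_total_cell_count_and_class_mixture(self, tmp_path):
        optics = OpticsConfig(frame_shape=(512, 512))
        make_dataset(tmp_path / "d", {"exponential": 8}, n_cells=20,
                     optics=optics, base_seed=3)
        import pandas as pd

        recs = pd.concat([
            pd.read_csv(tmp_path / "d" / f"img_{i:03d}_records.csv")
            for i in range(8)
        ])
        assert len(recs) == 8 * 20   # conservation: every requested cell placed
        frac_stalked = (recs["class"].isin(["stalked", "predivisional"])).mean()
        # multinomial 4-sigma band around the preset probability 0.60
        sd = np.sqrt(0.6 * 0.4 / len(recs))
        assert abs(frac_stalked - 0.60) < 4 * sd

    def test_roundtrip_io(self, tmp_path):
        optics = OpticsConfig(frame_shape=(128, 128))
        make_dataset(tmp_path / "d", {"exponential": 1}, n_cells=3,
                     optics=optics, base_seed=1)
        img = load_image(tmp_path / "d" / "img_000.tif")
        truth = load_truth(tmp_path / "d", "img_000")
        assert img.shape == (128, 128) and img.dtype == np.uint16
        assert truth.semantic_mask.shape == (128, 128)
        assert len(truth.records) == 3
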