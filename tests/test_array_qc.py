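"""Grid registration, spot measurement, mass quantification and QC reporting."""

import numpy as np
import pytest

from irisqc import array_qc, optics, synthgen
from irisqc.array_qc import QCThresholds, SpotMeasurement
from irisqc.chip_io import ChipImageSet, GridFit
from irisqc.layout import ArrayLayout, SpotAnnotation


@pytest.fixture(scope="module")
def chip():
    """One noise-free-ish synthetic 33-probe chip with two planted failures."""
    sc = synthgen.scenario_missing_spots(seed=11)
    image_set, truth = synthgen.generate_chip_images(sc)
    return sc, image_set, truth


@pytest.fixture(scope="module")
def qc_result(chip):
    sc, image_set, truth = chip
    report = array_qc.run_chip_qc(image_set, sc.optics)
    return sc, image_set, truth, report


def uniform_spot_image(spot_value=2000, bg_value=1000, sat_pixels=0):
    """Single centered spot of uniform intensity on a uniform background."""
    lay = ArrayLayout(
        n_rows=1, n_cols=1, pitch_um=225.0, spot_diameter_um=150.0, pixel_size_um=7.5,
        probe_map={(1, 1): SpotAnnotation("P")},
    )
    h = w = 40
    img = np.full((h, w), bg_value, dtype=np.uint16)
    ys, xs = np.ogrid[:h, :w]
    disk = (xs - 20) ** 2 + (ys - 20) ** 2 <= 10**2
    img[disk] = spot_value
    if sat_pixels:
        idx = np.argwhere(disk)[:sat_pixels]
        img[idx[:, 0], idx[:, 1]] = 65535
    iset = ChipImageSet(images=img[None].repeat(4, axis=0),
                        labels=(452.0, 518.0, 595.0, 632.0), layout=lay)
    iset.grid = GridFit((20.0, 20.0), lay.pitch_px, 0.0)
    return iset


class TestRegisterGrid:
    def test_recovers_planted_geometry(self, chip):
        sc, image_set, truth = chip
        grid = array_qc.register_grid(image_set)
        pitch = truth.pitch_px
        err = np.hypot(
            grid.origin_xy_px[0] - truth.grid_origin_xy_px[0],
            grid.origin_xy_px[1] - truth.grid_origin_xy_px[1],
        )
        assert err < 0.25 * pitch
        assert abs(grid.rotation_deg - truth.grid_rotation_deg) < 0.1

    def test_translation_equivariance(self, chip):
        sc, image_set, truth = chip
        grid0 = array_qc.register_grid(image_set)
        shifted = ChipImageSet(
            images=np.roll(image_set.images, (10, 10), axis=(1, 2)),
            labels=image_set.labels, layout=image_set.layout,
        )
        grid1 = array_qc.register_grid(shifted)
        assert grid1.origin_xy_px[0] - grid0.origin_xy_px[0] == pytest.approx(10.0, abs=0.3)
        assert grid1.origin_xy_px[1] - grid0.origin_xy_px[1] == pytest.approx(10.0, abs=0.3)
        assert grid1.rotation_deg == pytest.approx(grid0.rotation_deg, abs=0.05)
        assert grid1.pitch_px == grid0.pitch_px

    def test_rotation_equivariance_quarter_turn(self, chip):
        # rotating the image by 90 deg with the transposed layout must place
        # predicted centers on the rotated true centers
        sc, image_set, truth = chip
        lay = image_set.layout
        lay_t = ArrayLayout(
            n_rows=lay.n_cols, n_cols=lay.n_rows, pitch_um=lay.pitch_um,
            spot_diameter_um=lay.spot_diameter_um, pixel_size_um=lay.pixel_size_um,
            probe_map={
                (c, lay.n_rows + 1 - r): lay.probe_map[(r, c)]
                for r in range(1, lay.n_rows + 1) for c in range(1, lay.n_cols + 1)
            },
        )
        rot = ChipImageSet(
            images=np.rot90(image_set.images, k=-1, axes=(1, 2)).copy(),
            labels=image_set.labels, layout=lay_t,
        )
        grid_r = array_qc.register_grid(rot)
        h = image_set.shape[0]
        base = GridFit(truth.grid_origin_xy_px, truth.pitch_px, truth.grid_rotation_deg)
        errs = []
        for r in range(1, lay.n_rows + 1):
            for c in range(1, lay.n_cols + 1):
                x, y = base.center_px(r, c)
                # (x, y) -> (h-1-y, x) under clockwise quarter turn
                xr, yr = h - 1 - y, x
                xp, yp = grid_r.center_px(c, lay.n_rows + 1 - r)
                errs.append(np.hypot(xp - xr, yp - yr))
        assert np.median(errs) < 1.5

    def test_empty_image_raises_grid_not_found(self):
        lay = ArrayLayout(
            n_rows=3, n_cols=3, pitch_um=225.0, pixel_size_um=7.5,
            probe_map={(r, c): SpotAnnotation("P") for r in (1, 2, 3) for c in (1, 2, 3)},
        )
        rng = np.random.default_rng(0)
        flat = (28000 + 50 * rng.standard_normal((4, 120, 120))).astype(np.uint16)
        iset = ChipImageSet(images=flat, labels=(452.0, 518.0, 595.0, 632.0), layout=lay)
        with pytest.raises(array_qc.GridNotFoundError, match="detected"):
            array_qc.register_grid(iset)


class TestMeasureSpot:
    def test_uniform_spot_and_background_medians(self):
        iset = uniform_spot_image(2000, 1000)
        m = array_qc.measure_spot(iset, 1, 1)
        for wl in iset.labels:
            assert m.spot_median_intensity[wl] == 2000
            assert m.local_background_median[wl] == 1000
        assert m.saturation_fraction == 0.0
        assert m.circularity > 0.9

    def test_saturation_fraction_counts_full_scale_pixels(self):
        iset = uniform_spot_image(2000, 1000, sat_pixels=16)
        m = array_qc.measure_spot(iset, 1, 1)
        n_spot = int(m.spot_mask.sum())
        assert m.saturation_fraction == pytest.approx(16 / n_spot, abs=1.5 / n_spot)

    def test_elliptical_spot_fails_circularity(self):
        lay = ArrayLayout(
            n_rows=1, n_cols=1, pitch_um=300.0, spot_diameter_um=150.0, pixel_size_um=7.5,
            probe_map={(1, 1): SpotAnnotation("P")},
        )
        h = w = 44
        img = np.full((h, w), 1000, dtype=np.uint16)
        ys, xs = np.ogrid[:h, :w]
        ellipse = ((xs - 22) / 16.0) ** 2 + ((ys - 22) / 5.0) ** 2 <= 1.0
        img[ellipse] = 2000
        iset = ChipImageSet(images=img[None].repeat(4, axis=0),
                            labels=(452.0, 518.0, 595.0, 632.0), layout=lay)
        iset.grid = GridFit((22.0, 22.0), lay.pitch_px, 0.0)
        m = array_qc.measure_spot(iset, 1, 1)
        assert m.circularity < 0.7

    def test_requires_registration(self):
        iset = uniform_spot_image()
        iset.grid = None
        with pytest.raises(RuntimeError, match="register_grid"):
            array_qc.measure_spot(iset, 1, 1)


class TestSpotMass:
    def test_planted_mass_recovered_across_chip(self, qc_result):
        # healthy ~2 ng/mm^2 spots under 0.5% pixel noise and smooth oxide
        # variation: a few percent typical error, no gross outliers
        sc, image_set, truth, report = qc_result
        df = report.spots
        missing = truth.missing_positions
        rel = []
        for _, row in df[~df.blank].iterrows():
            if (row.row, row.col) in missing:
                continue
            planted = truth.mass_at((row.row, row.col))
            rel.append(abs(row.mass_ng_mm2 - planted) / planted)
        rel = np.array(rel)
        assert np.median(rel) < 0.03
        assert rel.max() < 0.10

    def test_single_clean_spot_within_two_percent(self, air_config):
        # noise-free single-spot render: the full pipeline recovers the
        # planted ~2 ng/mm^2 (5/3 nm biolayer) almost exactly
        sc = synthgen.scenario_clean_chip(seed=2, noise_sigma=0.0)
        sc.d_ox_variation_nm = 0.0
        sc.gain_spread = 0.0
        image_set, truth = synthgen.generate_chip_images(sc)
        report = array_qc.run_chip_qc(image_set, sc.optics)
        for _, row in report.spots.iterrows():
            if row.blank:
                continue
            planted = truth.mass_at((row.row, row.col))
            assert row.mass_ng_mm2 == pytest.approx(planted, rel=0.02)

    def test_spot_identical_to_background_reads_zero(self, air_config, lut_air):
        counts = {
            wl: 30000 * optics.reflectance(air_config, wl, 110.0, 0.0)
            for wl in air_config.wavelengths_nm
        }
        m = SpotMeasurement(
            row=1, col=1, probe="P", replicate_group="P", is_blank=False,
            centroid_px=(0, 0), diameter_um=150.0, circularity=1.0,
            spot_median_intensity=counts, local_background_median=dict(counts),
            saturation_fraction=0.0,
        )
        calib = optics.calibrate_gains(counts, lut_air)
        out = array_qc.spot_mass(m, lut_air, calib, air_config)
        assert out.mass_ng_mm2 == pytest.approx(0.0, abs=0.02)

    def test_background_above_spot_clips_to_zero_with_warning(self, air_config, lut_air):
        spot = {
            wl: 30000 * optics.reflectance(air_config, wl, 110.0, 0.0)
            for wl in air_config.wavelengths_nm
        }
        bg = {
            wl: 30000 * optics.reflectance(air_config, wl, 110.0, 0.5)
            for wl in air_config.wavelengths_nm
        }
        m = SpotMeasurement(
            row=1, col=1, probe="P", replicate_group="P", is_blank=False,
            centroid_px=(0, 0), diameter_um=150.0, circularity=1.0,
            spot_median_intensity=spot, local_background_median=bg,
            saturation_fraction=0.0,
        )
        calib = optics.calibrate_gains(
            {wl: 30000 * optics.reflectance(air_config, wl, 110.0, 0.0)
             for wl in air_config.wavelengths_nm},
            lut_air,
        )
        with pytest.warns(UserWarning, match="background exceeds"):
            out = array_qc.spot_mass(m, lut_air, calib, air_config)
        assert out.mass_ng_mm2 == 0.0
        assert out.mass_raw_ng_mm2 < 0
        assert "negative_differential" in out.flags

    def test_mass_monotone_in_planted_thickness(self, air_config, lut_air):
        # increasing planted biolayer never decreases reported mass (noise-free)
        calib_counts = {
            wl: 30000 * optics.reflectance(air_config, wl, 110.0, 0.0)
            for wl in air_config.wavelengths_nm
        }
        calib = optics.calibrate_gains(calib_counts, lut_air)
        last = -1.0
        for d in np.linspace(0.0, 5.0, 21):
            spot = {
                wl: 30000 * optics.reflectance(air_config, wl, 110.0, d)
                for wl in air_config.wavelengths_nm
            }
            m = SpotMeasurement(
                row=1, col=1, probe="P", replicate_group="P", is_blank=False,
                centroid_px=(0, 0), diameter_um=150.0, circularity=1.0,
                spot_median_intensity=spot, local_background_median=dict(calib_counts),
                saturation_fraction=0.0,
            )
            out = array_qc.spot_mass(m, lut_air, calib, air_config)
            assert out.mass_ng_mm2 >= last - 1e-9
            last = out.mass_ng_mm2


def make_measurement(mass, saturation=0.0, circularity=1.0, diameter=150.0):
    return SpotMeasurement(
        row=1, col=1, probe="P", replicate_group="P", is_blank=False,
        centroid_px=(0, 0), diameter_um=diameter, circularity=circularity,
        spot_median_intensity={}, local_background_median={},
        saturation_fraction=saturation, mass_ng_mm2=mass,
    )


class TestClassifySpot:
    def test_below_absolute_floor_is_missing(self):
        m = make_measurement(0.05)
        m._expected_diameter_um = 150.0
        assert array_qc.classify_spot(m, [0.05, 2.0], QCThresholds()) == "missing"

    def test_low_density_against_group_median(self):
        # 0.4 ng/mm^2 in a ~2 ng/mm^2 group: flagged low-density (0.4 < 0.5 * 2)
        m = make_measurement(0.4)
        m._expected_diameter_um = 150.0
        assert array_qc.classify_spot(m, [0.4, 2.0, 2.0], QCThresholds()) == "low_density"

    def test_saturation_takes_precedence_over_low_density(self):
        m = make_measurement(0.4, saturation=0.2)
        m._expected_diameter_um = 150.0
        assert array_qc.classify_spot(m, [0.4, 2.0, 2.0], QCThresholds()) == "saturated"

    def test_irregular_shape_flagged(self):
        m = make_measurement(2.0, circularity=0.5)
        m._expected_diameter_um = 150.0
        assert array_qc.classify_spot(m, [2.0, 2.0], QCThresholds()) == "irregular"

    def test_healthy_spot_ok(self):
        m = make_measurement(2.0)
        m._expected_diameter_um = 150.0
        assert array_qc.classify_spot(m, [2.0, 2.1], QCThresholds()) == "ok"

    def test_zero_median_with_nonzero_members_inconsistent(self):
        m = make_measurement(1.0)
        m._expected_diameter_um = 150.0
        with pytest.raises(ValueError, match="median"):
            array_qc.classify_spot(m, [0.0, 0.0, 1.0, 0.0, 0.0], QCThresholds())


class TestQCReport:
    def test_planted_failures_flagged_exactly(self, qc_result):
        sc, image_set, truth, report = qc_result
        assert report.verdict == "fail"
        flagged = {
            (r.row, r.col) for _, r in report.spots.iterrows() if r.status == "missing"
        }
        assert flagged == truth.missing_positions
        assert set(report.failing_probes) == set(synthgen.DEFAULT_FAILED_PROBES)

    def test_report_covers_every_position_once(self, qc_result):
        sc, image_set, truth, report = qc_result
        lay = image_set.layout
        seen = list(zip(report.spots.row, report.spots.col))
        assert sorted(seen) == sorted(lay.positions)
        assert len(seen) == len(set(seen))
        groups = set(report.probes.probe)
        assert groups == set(lay.groups)

    def test_clean_chip_passes(self):
        sc = synthgen.scenario_clean_chip(seed=5)
        image_set, truth = synthgen.generate_chip_images(sc)
        report = array_qc.run_chip_qc(image_set, sc.optics)
        assert report.verdict == "pass"
        assert report.failing_probes == []

    def test_partial_replicate_group_warns_not_fails(self):
        sc = synthgen.scenario_clean_chip(seed=5)
        pos = (1, 1)
        probe = sc.layout.annotation(*pos).probe
        sc.low_density = {pos: 0.2}
        image_set, truth = synthgen.generate_chip_images(sc)
        report = array_qc.run_chip_qc(image_set, sc.optics)
        assert probe in report.partial_probes
        assert report.verdict == "pass_with_warnings"

    def test_json_and_csv_outputs(self, qc_result, tmp_path):
        *_, report = qc_result
        report.to_csv(tmp_path / "spots.csv")
        text = report.to_json(tmp_path / "report.json")
        assert "failing_probes" in text
        assert (tmp_path / "spots.csv").exists()
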