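"""Spot gridding, segmentation, QC metrics and chip-level reporting.

The QC workflow on a four-color dry-chip scan is::

    register_grid -> measure_all -> calibrate -> spot_mass -> classify -> qc_report

Spot intensity, size, saturation level and local background are measured per
spot; the optics inversion turns the spot-vs-background reflectance
differential into surface mass density; thresholds then classify each spot as
ok / missing / low-density / saturated / irregular, and the chip report
aggregates replicate groups and issues a pass/fail verdict.  Statistics use
medians throughout (robust to comets and debris) and the background is a
per-spot local annulus, mirroring the differential spot-minus-background
logic of the readout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from . import optics
from .chip_io import ChipImageSet, GridFit
from .optics import ChipCalibration, OpticsConfig, ReflectanceLUT


class GridNotFoundError(RuntimeError):
    """Too few detectable spots to register the grid."""


STATUS_OK = "ok"
STATUS_MISSING = "missing"
STATUS_LOW_DENSITY = "low_density"
STATUS_SATURATED = "saturated"
STATUS_IRREGULAR = "irregular"


@dataclass
class QCThresholds:
    """Classification thresholds; defaults flag the ~0.4 ng/mm^2 failed-probe
    regime against a ~2 ng/mm^2 healthy group."""

    missing_abs_ng_mm2: float = 0.2
    low_density_fraction_of_group_median: float = 0.5
    saturation_fraction_max: float = 0.01
    circularity_min: float = 0.7
    diameter_tolerance_fraction: float = 0.35
    replicate_cv_max: float = 0.25
    chip_fail_nonok_fraction: float = 0.25
    fail_on_partial_groups: bool = False  # default: pass-with-warnings

    def __post_init__(self) -> None:
        for name in (
            "low_density_fraction_of_group_median",
            "saturation_fraction_max",
            "circularity_min",
            "diameter_tolerance_fraction",
            "replicate_cv_max",
            "chip_fail_nonok_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.missing_abs_ng_mm2 < 0:
            raise ValueError("missing_abs_ng_mm2 must be >= 0")


@dataclass
class SpotMeasurement:
    """Per-spot QC record; mass fields are filled by :func:`spot_mass`."""

    row: int
    col: int
    probe: str
    replicate_group: str
    is_blank: bool
    centroid_px: tuple[float, float]
    diameter_um: float
    circularity: float
    spot_median_intensity: dict[float, float]
    local_background_median: dict[float, float]
    saturation_fraction: float
    d_bio_nm: float | None = None
    d_bio_background_nm: float | None = None
    mass_ng_mm2: float | None = None
    mass_raw_ng_mm2: float | None = None
    fit_residual: float | None = None
    status: str = STATUS_OK
    flags: list[str] = field(default_factory=list)
    spot_mask: np.ndarray | None = field(default=None, repr=False)
    background_mask: np.ndarray | None = field(default=None, repr=False)


# --------------------------------------------------------------------------
# grid registration


def _detection_image(image_set: ChipImageSet) -> np.ndarray:
    if image_set.kind == "time":
        img = image_set.images[0].astype(float)
    else:
        img = image_set.images.astype(float).mean(axis=0)
    return img


def _bandpass(img: np.ndarray, spot_radius_px: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass tuned to the spot size, rectified.

    Spots may be brighter or darker than the background depending on where
    the biolayer moves the interference curve, so the absolute response is
    used.
    """
    lo = ndimage.gaussian_filter(img, sigma=spot_radius_px / 2.0)
    hi = ndimage.gaussian_filter(img, sigma=spot_radius_px * 2.0)
    return np.abs(lo - hi)


def detect_spots(image_set: ChipImageSet) -> np.ndarray:
    """Blob centroids (x, y) via band-pass filtering + local maxima."""
    return detect_points(_detection_image(image_set), image_set.layout)


def detect_points(img: np.ndarray, layout) -> np.ndarray:
    """Blob centroids (x, y) in a single 2-D image."""
    resp = _bandpass(img, layout.spot_radius_px)
    # detection threshold from propagated pixel noise: sigma of white noise
    # after a Gaussian of width s falls to sigma_px / (2 s sqrt(pi)); local
    # maxima of pure noise sit ~2.5 of those sigmas, real spots far higher.
    # sigma_px from robust horizontal differences (insensitive to smooth
    # illumination structure and to the spots themselves).
    sigma_px = 1.4826 * float(np.median(np.abs(np.diff(img, axis=1)))) / np.sqrt(2.0)
    sigma_dog = sigma_px / (2.0 * np.sqrt(np.pi) * (layout.spot_radius_px / 2.0))
    peaks = peak_local_max(
        resp,
        min_distance=max(1, int(round(0.7 * layout.pitch_px))),
        threshold_abs=6.0 * sigma_dog + 1e-6,
        # filter edge effects can fabricate peaks along the border; real spots
        # sit at least one spot radius inside the chip
        exclude_border=max(1, int(round(layout.spot_radius_px))),
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    # refine each peak to the intensity-weighted centroid of its neighborhood
    cents = []
    r = int(round(layout.spot_radius_px))
    for py, px in peaks:
        y0, y1 = max(0, py - r), min(img.shape[0], py + r + 1)
        x0, x1 = max(0, px - r), min(img.shape[1], px + r + 1)
        patch = resp[y0:y1, x0:x1]
        tot = patch.sum()
        if tot <= 0:
            cents.append((px, py))
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        cents.append(((xs * patch).sum() / tot, (ys * patch).sum() / tot))
    return np.asarray(cents)


def _estimate_rotation(points: np.ndarray, pitch_px: float) -> float:
    """Grid rotation from nearest-neighbor displacement angles folded mod 90 deg."""
    angles = []
    for i in range(len(points)):
        d = points - points[i]
        dist = np.hypot(d[:, 0], d[:, 1])
        near = (dist > 0.5 * pitch_px) & (dist < 1.5 * pitch_px)
        for dx, dy in d[near]:
            a = np.rad2deg(np.arctan2(dy, dx))
            a = (a + 45.0) % 90.0 - 45.0  # fold to (-45, 45]
            angles.append(a)
    if not angles:
        return 0.0
    return float(np.median(angles))


def register_grid(image_set: ChipImageSet, max_rotation_deg: float = 5.0) -> GridFit:
    """Fit grid origin, pitch and rotation to detected blob centroids.

    Rotation comes from a principal-axis (nearest-neighbor angle) fit; the
    origin from least squares over the assignment of detected blobs to grid
    nodes, iterated once after re-assignment.  Raises
    :class:`GridNotFoundError` when fewer than 25% of the expected spots are
    detected.
    """
    layout = image_set.layout
    expected = sum(1 for p in layout.positions if not layout.annotation(*p).is_blank)
    points = detect_spots(image_set)
    if len(points) < max(1, int(np.ceil(0.25 * expected))):
        raise GridNotFoundError(
            f"grid not found: detected {len(points)} blobs, "
            f"expected at least 25% of {expected} spots"
        )
    pitch = layout.pitch_px
    theta = np.clip(_estimate_rotation(points, pitch), -max_rotation_deg, max_rotation_deg)

    origin = None
    for _ in range(3):
        th = np.deg2rad(theta)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        local = points @ rot.T  # de-rotated coordinates
        if origin is None:
            # phase of the lattice, per axis, via circular mean mod pitch
            phase = []
            for ax in range(2):
                ang = 2.0 * np.pi * (local[:, ax] % pitch) / pitch
                mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
                phase.append((mean % (2.0 * np.pi)) * pitch / (2.0 * np.pi))
            ref = np.array(phase)
        else:
            ref = origin @ rot.T
        idx = np.round((local - ref) / pitch).astype(int)
        # anchor the integer lattice per axis: among shifts that keep the most
        # detections inside the layout extent, choose the one whose implied
        # grid sits most centered within the image (the borders disambiguate
        # when an edge row or column went undetected)
        dims = (image_set.shape[1], image_set.shape[0])  # (W, H) ~ (x, y)
        for ax, n_ax in ((0, layout.n_cols), (1, layout.n_rows)):
            lo, hi = int(idx[:, ax].min()), int(idx[:, ax].max())
            candidates = range(min(hi - n_ax + 1, lo), lo + 1)
            best_s, best_key = lo, None
            for s in candidates:
                count = int(np.count_nonzero((idx[:, ax] >= s) & (idx[:, ax] <= s + n_ax - 1)))
                o = float(np.median(local[:, ax] - (idx[:, ax] - s) * pitch))
                extent_mid = o + 0.5 * (n_ax - 1) * pitch
                inside = (o > -0.5 * pitch) and (o + (n_ax - 1) * pitch < dims[ax] - 1 + 0.5 * pitch)
                key = (-count, not inside, abs(extent_mid - 0.5 * (dims[ax] - 1)))
                if best_key is None or key < best_key:
                    best_s, best_key = s, key
            idx[:, ax] -= best_s
        # clip to layout extent (cols along x, rows along y)
        idx[:, 0] = np.clip(idx[:, 0], 0, layout.n_cols - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, layout.n_rows - 1)
        nodes = idx * pitch
        origin_local = np.median(local - nodes, axis=0)
        origin = origin_local @ rot  # back to image coordinates
        # refine rotation by Procrustes between node offsets and points
        pc = points - points.mean(axis=0)
        nc = nodes - nodes.mean(axis=0)
        num = np.sum(nc[:, 0] * pc[:, 1] - nc[:, 1] * pc[:, 0])
        den = np.sum(nc[:, 0] * pc[:, 0] + nc[:, 1] * pc[:, 1])
        if den != 0:
            theta_new = np.rad2deg(np.arctan2(num, den))
            theta = float(np.clip(theta_new, -max_rotation_deg, max_rotation_deg))

    fit = GridFit(
        origin_xy_px=(float(origin[0]), float(origin[1])),
        pitch_px=float(pitch),
        rotation_deg=float(theta),
        n_detected=int(len(points)),
    )
    image_set.grid = fit
    return fit


# --------------------------------------------------------------------------
# per-spot measurement


def _disk_mask(shape, cx, cy, radius) -> np.ndarray:
    ys, xs = np.ogrid[: shape[0], : shape[1]]
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2


def _cell_mask(shape, cx, cy, half) -> np.ndarray:
    ys, xs = np.ogrid[: shape[0], : shape[1]]
    return (np.abs(xs - cx) <= half) & (np.abs(ys - cy) <= half)


def _mask_stats(mask: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Centroid (x, y), equivalent diameter (px) and circularity of a mask."""
    ys, xs = np.nonzero(mask)
    area = len(xs)
    cx, cy = float(xs.mean()), float(ys.mean())
    diameter = 2.0 * np.sqrt(area / np.pi)
    # perimeter via crofton-style edge count
    from skimage.measure import perimeter as sk_perimeter

    per = sk_perimeter(mask, neighborhood=4)
    if per <= 0:
        return (cx, cy), diameter, 1.0
    circ = 4.0 * np.pi * area / per**2
    return (cx, cy), diameter, float(min(1.0, circ))


def measure_spot(image_set: ChipImageSet, row: int, col: int) -> SpotMeasurement:
    """Geometry, intensities and saturation for one grid position.

    The spot mask starts as the disk of expected diameter and is refined by
    thresholding against the local background within the grid cell; the
    background is the annulus between 1.2x and 1.8x the spot radius, clipped
    to the cell so neighboring spots are excluded.  Medians are used for both.
    """
    if image_set.grid is None:
        raise RuntimeError("register_grid must run before measure_spot")
    layout = image_set.layout
    ann = layout.annotation(row, col)
    cx, cy = image_set.grid.center_px(row, col)
    h, w = image_set.shape
    r0 = layout.spot_radius_px
    half = 0.5 * image_set.grid.pitch_px

    flags = []
    if cx - half < 0 or cy - half < 0 or cx + half > w - 1 or cy + half > h - 1:
        flags.append("edge")

    cell = _cell_mask((h, w), cx, cy, half)
    disk = _disk_mask((h, w), cx, cy, r0) & cell
    annulus = (
        _disk_mask((h, w), cx, cy, 1.8 * r0)
        & ~_disk_mask((h, w), cx, cy, 1.2 * r0)
        & cell
    )
    if not disk.any() or not annulus.any():
        flags.append("edge")
        disk = _disk_mask((h, w), min(max(cx, r0), w - 1 - r0), min(max(cy, r0), h - 1 - r0), r0)
        annulus = ~disk & _cell_mask(
            (h, w), min(max(cx, half), w - 1 - half), min(max(cy, half), h - 1 - half), half
        )

    ref = _detection_image(image_set)
    bg_med = float(np.median(ref[annulus]))
    spot_med0 = float(np.median(ref[disk]))
    contrast = spot_med0 - bg_med
    # refine the mask only when the spot actually stands out of the pixel
    # noise, otherwise geometry defaults to the nominal disk
    noise_sigma = 1.4826 * float(np.median(np.abs(ref[annulus] - bg_med))) + 1e-12

    mask = disk
    centroid, diameter_px, circularity = (cx, cy), 2 * r0, 1.0
    if abs(contrast) > 3.0 * noise_sigma:
        thr = bg_med + 0.5 * contrast
        fg = (ref >= thr) if contrast > 0 else (ref <= thr)
        fg &= cell
        lab, _ = ndimage.label(fg)
        lab_at = lab[int(round(cy)), int(round(cx))] if (0 <= int(round(cy)) < h and 0 <= int(round(cx)) < w) else 0
        if lab_at > 0:
            region = lab == lab_at
            if region.sum() >= 0.2 * max(1, disk.sum()):
                mask = region
                centroid, diameter_px, circularity = _mask_stats(region)

    sat_level = image_set.saturation_level
    n_spot_px = int(mask.sum())
    sat_counts = [
        int(np.count_nonzero(image_set.images[k][mask] >= sat_level))
        for k in range(image_set.images.shape[0])
    ]
    saturation_fraction = max(sat_counts) / max(1, n_spot_px)

    # intensity statistics from the spot interior: printed spots have a soft
    # intensity ramp at their rim, so the mask is eroded by ~2 px before
    # taking medians (the full mask still defines geometry and saturation)
    interior = ndimage.binary_erosion(mask, iterations=2)
    if not interior.any():
        interior = mask
    spot_medians = {
        lb: float(np.median(image_set.images[k][interior].astype(float)))
        for k, lb in enumerate(image_set.labels)
    }
    bg_medians = {
        lb: float(np.median(image_set.images[k][annulus].astype(float)))
        for k, lb in enumerate(image_set.labels)
    }

    return SpotMeasurement(
        row=row,
        col=col,
        probe=ann.probe,
        replicate_group=ann.group,
        is_blank=ann.is_blank,
        centroid_px=centroid,
        diameter_um=float(diameter_px * layout.pixel_size_um),
        circularity=circularity,
        spot_median_intensity=spot_medians,
        local_background_median=bg_medians,
        saturation_fraction=float(saturation_fraction),
        flags=flags,
        spot_mask=mask,
        background_mask=annulus,
    )


def measure_all(image_set: ChipImageSet) -> list[SpotMeasurement]:
    """Measure every layout position (blanks included, for report completeness)."""
    return [measure_spot(image_set, r, c) for r, c in image_set.layout.positions]


# --------------------------------------------------------------------------
# mass quantification


def background_mask(image_set: ChipImageSet, margin_factor: float = 1.4) -> np.ndarray:
    """Spot-free chip area: everything beyond ``margin_factor`` spot radii of
    any expected spot center."""
    if image_set.grid is None:
        raise RuntimeError("register_grid must run first")
    h, w = image_set.shape
    keep = np.ones((h, w), dtype=bool)
    r = image_set.layout.spot_radius_px * margin_factor
    for row, col in image_set.layout.positions:
        cx, cy = image_set.grid.center_px(row, col)
        keep &= ~_disk_mask((h, w), cx, cy, r)
    return keep


def calibrate_chip(
    image_set: ChipImageSet,
    lut: ReflectanceLUT,
) -> ChipCalibration:
    """Chip-level oxide thickness + per-channel gains from the spot-free area."""
    mask = background_mask(image_set)
    if not mask.any():
        raise RuntimeError("no spot-free background area available for calibration")
    med = {
        lb: float(np.median(image_set.images[k][mask].astype(float)))
        for k, lb in enumerate(image_set.labels)
    }
    # chips are manufactured near the nominal oxide; a +/-10 nm chip-level
    # window keeps residual gain-imbalance from dragging d_ox (and with it the
    # d_bio sensitivity scale) far from truth
    nominal = lut.config.oxide_nominal_nm
    window = (
        max(float(lut.d_ox_grid_nm[0]), nominal - 10.0),
        min(float(lut.d_ox_grid_nm[-1]), nominal + 10.0),
    )
    return optics.calibrate_gains(med, lut, d_ox_window_nm=window)


def spot_mass(
    measurement: SpotMeasurement,
    lut: ReflectanceLUT,
    calibration: ChipCalibration,
    config: OpticsConfig,
    residual_ceiling: float = 0.02,
) -> SpotMeasurement:
    """Fill d_bio and mass from the spot and local-background medians.

    Both regions are inverted with the chip-level oxide thickness held fixed
    and only d_bio free; the reported mass is the clipped differential
    ``c * (d_bio_spot - d_bio_background)`` with the raw (possibly negative)
    differential retained.
    """
    wavelengths = lut.wavelengths_nm
    gains = calibration.gains_vector(wavelengths)
    spot_obs = [measurement.spot_median_intensity[w] for w in wavelengths]
    bg_obs = [measurement.local_background_median[w] for w in wavelengths]
    # local oxide reference: the chip-level oxide varies smoothly by a little,
    # so the annulus (assumed probe-free) pins the local d_ox in a narrow
    # window around the chip calibration; the spot then has only d_bio free
    ox_lo = max(float(lut.d_ox_grid_nm[0]), calibration.d_ox_nm - 5.0)
    ox_hi = min(float(lut.d_ox_grid_nm[-1]), calibration.d_ox_nm + 5.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_bg = optics.fit_thickness(
            bg_obs, lut, window=((ox_lo, ox_hi), (0.0, 0.0)), gains=gains
        )
        d_ox_local = fit_bg.d_ox_nm
        fit_spot = optics.fit_thickness(
            spot_obs,
            lut,
            window=((d_ox_local, d_ox_local), (0.0, float(lut.d_bio_grid_nm[-1]))),
            gains=gains,
        )
        raw_nm = fit_spot.d_bio_nm
        if fit_spot.d_bio_nm <= float(lut.d_bio_grid_nm[0]) + 1e-9:
            # spot may sit *below* its local background; recover the signed
            # differential through the oxide-equivalent thickness of the spot
            fit_spot_eq = optics.fit_thickness(
                spot_obs, lut, window=((ox_lo, ox_hi), (0.0, 0.0)), gains=gains
            )
            slope_ratio = _oxide_to_bio_slope_ratio(config, lut, d_ox_local)
            raw_nm = (fit_spot_eq.d_ox_nm - d_ox_local) * slope_ratio
    measurement.d_bio_nm = fit_spot.d_bio_nm
    measurement.d_bio_background_nm = d_ox_local - calibration.d_ox_nm
    raw = config.mass_per_nm * raw_nm
    measurement.mass_raw_ng_mm2 = float(raw)
    measurement.mass_ng_mm2 = float(max(0.0, raw))
    if raw < 0:
        measurement.flags.append("negative_differential")
        warnings.warn(
            f"spot ({measurement.row},{measurement.col}): background exceeds spot signal",
            stacklevel=2,
        )
    measurement.fit_residual = fit_spot.residual
    # residual is in detector counts here; normalize by the background level
    rel = fit_spot.residual / max(1e-12, np.mean(gains) * 0.25)
    if rel > residual_ceiling:
        measurement.flags.append("unreliable_fit")
    if fit_spot.window_edge:
        measurement.flags.append("window_edge")
    return measurement


def _oxide_to_bio_slope_ratio(
    config: OpticsConfig, lut: ReflectanceLUT, d_ox_nm: float
) -> float:
    """Mean over channels of (dR/dd_ox) / (dR/dd_bio): converts an
    oxide-equivalent thickness excess into biolayer nanometres (close to 1,
    since the film indices nearly match)."""
    ratios = []
    for wl in lut.wavelengths_nm:
        h = 0.05
        r_ox = (
            optics.reflectance(config, wl, d_ox_nm + h, 0.0)
            - optics.reflectance(config, wl, d_ox_nm - h, 0.0)
        ) / (2 * h)
        r_bio = optics.reflectance_slope(config, wl, d_ox_nm, 0.05)
        if abs(r_bio) > 1e-9:
            ratios.append(r_ox / r_bio)
    return float(np.mean(ratios)) if ratios else 1.0


# --------------------------------------------------------------------------
# classification and report


def classify_spot(
    measurement: SpotMeasurement,
    group_masses: np.ndarray,
    thresholds: QCThresholds,
) -> str:
    """Status with precedence missing > saturated > irregular > low_density > ok."""
    if measurement.is_blank:
        measurement.status = STATUS_OK
        return measurement.status
    if measurement.mass_ng_mm2 is None:
        raise RuntimeError("spot_mass must run before classify_spot")
    m = measurement.mass_ng_mm2
    group_masses = np.asarray(group_masses, dtype=float)
    median = float(np.median(group_masses)) if group_masses.size else 0.0
    if median == 0.0 and np.any(group_masses > 0):
        raise ValueError("replicate group median is zero with nonzero member masses")

    if m < thresholds.missing_abs_ng_mm2:
        status = STATUS_MISSING
    elif measurement.saturation_fraction > thresholds.saturation_fraction_max:
        status = STATUS_SATURATED
    elif (
        measurement.circularity < thresholds.circularity_min
        or abs(measurement.diameter_um - measurement_expected_diameter(measurement))
        > thresholds.diameter_tolerance_fraction * measurement_expected_diameter(measurement)
    ):
        status = STATUS_IRREGULAR
    elif median > 0 and m < thresholds.low_density_fraction_of_group_median * median:
        status = STATUS_LOW_DENSITY
    else:
        status = STATUS_OK
    measurement.status = status
    return status


def measurement_expected_diameter(measurement: SpotMeasurement) -> float:
    """Expected printed diameter; stashed on the measurement by measure_all."""
    return getattr(measurement, "_expected_diameter_um", 150.0)


def classify_all(
    measurements: list[SpotMeasurement],
    layout_spot_diameter_um: float,
    thresholds: QCThresholds | None = None,
) -> None:
    """Classify every measured spot in the context of its replicate group."""
    thresholds = thresholds or QCThresholds()
    by_group: dict[str, list[SpotMeasurement]] = {}
    for m in measurements:
        m._expected_diameter_um = layout_spot_diameter_um
        if not m.is_blank:
            by_group.setdefault(m.replicate_group, []).append(m)
    for group, members in by_group.items():
        masses = np.array([m.mass_ng_mm2 for m in members], dtype=float)
        for m in members:
            classify_spot(m, masses, thresholds)
    for m in measurements:
        if m.is_blank:
            m.status = STATUS_OK


@dataclass
class QCReport:
    """Chip-level QC outcome: per-spot table, per-probe aggregates, verdict."""

    spots: pd.DataFrame
    probes: pd.DataFrame
    verdict: str  # "pass" | "pass_with_warnings" | "fail"
    failing_probes: list[str]
    partial_probes: list[str]
    failure_reasons: list[str]

    @property
    def passed(self) -> bool:
        return self.verdict != "fail"

    def to_csv(self, path) -> None:
        self.spots.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "verdict": self.verdict,
            "failing_probes": self.failing_probes,
            "partial_probes": self.partial_probes,
            "failure_reasons": self.failure_reasons,
            "probes": self.probes.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def qc_report(
    measurements: list[SpotMeasurement],
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Aggregate classified measurements into the chip QC report.

    The chip fails if any probe's replicate group is entirely missing, or if
    more than ``chip_fail_nonok_fraction`` of non-blank spots are non-ok.
    Groups with some (not all) flagged replicates are listed as partial;
    by default they downgrade the verdict to pass-with-warnings only.
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    for m in measurements:
        rows.append(
            {
                "row": m.row,
                "col": m.col,
                "probe": m.probe if not m.is_blank else "",
                "replicate_group": m.replicate_group if not m.is_blank else "",
                "blank": m.is_blank,
                "centroid_x_px": m.centroid_px[0],
                "centroid_y_px": m.centroid_px[1],
                "diameter_um": m.diameter_um,
                "circularity": m.circularity,
                "saturation_fraction": m.saturation_fraction,
                "d_bio_nm": m.d_bio_nm,
                "mass_ng_mm2": m.mass_ng_mm2,
                "mass_raw_ng_mm2": m.mass_raw_ng_mm2,
                "status": m.status,
                "flags": ";".join(m.flags),
            }
        )
    spots_df = pd.DataFrame(rows)

    agg_rows = []
    failing, partial = [], []
    by_group: dict[str, list[SpotMeasurement]] = {}
    for m in measurements:
        if not m.is_blank:
            by_group.setdefault(m.replicate_group, []).append(m)
    for group, members in sorted(by_group.items()):
        masses = np.array([m.mass_ng_mm2 for m in members], dtype=float)
        statuses = [m.status for m in members]
        mean = float(masses.mean())
        sd = float(masses.std(ddof=1)) if len(masses) > 1 else 0.0
        cv = sd / mean if mean > 0 else np.nan
        n_ok = statuses.count(STATUS_OK)
        if all(s == STATUS_MISSING for s in statuses):
            probe_status = "failed"
            failing.append(group)
        elif n_ok < len(members):
            probe_status = "partial"
            partial.append(group)
        elif np.isfinite(cv) and cv > thresholds.replicate_cv_max:
            probe_status = "high_cv"
            partial.append(group)
        else:
            probe_status = "ok"
        agg_rows.append(
            {
                "probe": group,
                "n_replicates": len(members),
                "mass_mean_ng_mm2": mean,
                "mass_sd_ng_mm2": sd,
                "mass_cv": cv if np.isfinite(cv) else None,
                "n_ok": n_ok,
                "n_missing": statuses.count(STATUS_MISSING),
                "status": probe_status,
            }
        )
    probes_df = pd.DataFrame(agg_rows)

    non_blank = [m for m in measurements if not m.is_blank]
    n_nonok = sum(1 for m in non_blank if m.status != STATUS_OK)
    frac_nonok = n_nonok / max(1, len(non_blank))

    reasons = []
    if failing:
        reasons.append(f"probes entirely missing: {', '.join(failing)}")
    if frac_nonok > thresholds.chip_fail_nonok_fraction:
        reasons.append(
            f"{frac_nonok:.0%} of spots non-ok exceeds "
            f"{thresholds.chip_fail_nonok_fraction:.0%} limit"
        )
    if thresholds.fail_on_partial_groups and partial:
        reasons.append(f"partial replicate groups: {', '.join(partial)}")

    if reasons:
        verdict = "fail"
    elif partial or n_nonok:
        verdict = "pass_with_warnings"
    else:
        verdict = "pass"
    return QCReport(spots_df, probes_df, verdict, failing, partial, reasons)


def run_chip_qc(
    image_set: ChipImageSet,
    config: OpticsConfig,
    thresholds: QCThresholds | None = None,
    lut: ReflectanceLUT | None = None,
) -> QCReport:
    """Convenience pipeline: register, measure, calibrate, quantify, classify."""
    if lut is None:
        lut = optics.build_lut(config)
    register_grid(image_set)
    measurements = measure_all(image_set)
    calibration = calibrate_chip(image_set, lut)
    for m in measurements:
        if not m.is_blank:
            spot_mass(m, lut, calibration, config)
        else:
            m.mass_ng_mm2 = 0.0
            m.mass_raw_ng_mm2 = 0.0
    classify_all(measurements, image_set.layout.spot_diameter_um, thresholds)
    return qc_report(measurements, thresholds)
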