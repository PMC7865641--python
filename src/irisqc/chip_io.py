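"""Image containers and TIFF I/O.

Chip acquisitions are multi-page 16-bit grayscale TIFFs: one page per LED
wavelength for static (four-color) scans, or one page per time point for
single-wavelength binding movies.  A YAML sidecar carries the page-to-label
mapping (wavelengths in nm or timestamps in s), the bit depth and the pixel
size, since TIFF alone does not standardize either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .layout import ArrayLayout


@dataclass
class GridFit:
    """Registered grid: pixel position of spot (1,1) plus pitch and rotation."""

    origin_xy_px: tuple[float, float]
    pitch_px: float
    rotation_deg: float
    n_detected: int = 0

    def center_px(self, row: int, col: int) -> tuple[float, float]:
        """Predicted center (x, y) of a 1-based grid position."""
        th = np.deg2rad(self.rotation_deg)
        u = (col - 1) * self.pitch_px
        v = (row - 1) * self.pitch_px
        x = self.origin_xy_px[0] + u * np.cos(th) - v * np.sin(th)
        y = self.origin_xy_px[1] + u * np.sin(th) + v * np.cos(th)
        return float(x), float(y)


@dataclass
class ChipImageSet:
    """A registered set of chip images sharing one layout.

    ``kind`` is ``"wavelength"`` (four-color scan; labels are wavelengths in
    nm) or ``"time"`` (single-wavelength movie; labels are timestamps in s,
    with the acquisition wavelength in ``wavelength_nm``).
    """

    images: np.ndarray  # (n_pages, H, W)
    labels: tuple[float, ...]
    layout: ArrayLayout
    kind: str = "wavelength"
    bit_depth: int = 16
    wavelength_nm: float | None = None
    grid: GridFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_pages, H, W) array")
        if len(self.labels) != self.images.shape[0]:
            raise ValueError("one label per image page required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.kind not in ("wavelength", "time"):
            raise ValueError("kind must be 'wavelength' or 'time'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1

    def channel(self, label: float) -> np.ndarray:
        try:
            return self.images[self.labels.index(label)]
        except ValueError as exc:
            raise KeyError(f"no page labelled {label}") from exc


def save_image_set(image_set: ChipImageSet, tiff_path, sidecar_path=None) -> None:
    """Write a multi-page TIFF plus its YAML sidecar."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".yaml")
    tifffile.imwrite(
        tiff_path, image_set.images.astype(np.uint16), photometric="minisblack"
    )
    meta = {
        "kind": image_set.kind,
        "labels": [float(x) for x in image_set.labels],
        "bit_depth": image_set.bit_depth,
        "pixel_size_um": image_set.layout.pixel_size_um,
    }
    if image_set.wavelength_nm is not None:
        meta["wavelength_nm"] = float(image_set.wavelength_nm)
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_image_set(tiff_path, layout: ArrayLayout, sidecar_path=None) -> ChipImageSet:
    """Read a multi-page TIFF and its YAML sidecar back into a ChipImageSet.

    Without a sidecar, pages are assumed to be a four-color scan in ascending
    default wavelength order.
    """
    tiff_path = Path(tiff_path)
    images = tifffile.imread(tiff_path)
    if images.ndim == 2:
        images = images[None]
    if sidecar_path is None:
        candidate = tiff_path.with_suffix(".yaml")
        sidecar_path = candidate if candidate.exists() else None
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        return ChipImageSet(
            images=images,
            labels=tuple(float(x) for x in meta["labels"]),
            layout=layout,
            kind=meta.get("kind", "wavelength"),
            bit_depth=int(meta.get("bit_depth", 16)),
            wavelength_nm=meta.get("wavelength_nm"),
        )
    from . import constants

    if images.shape[0] != len(constants.DEFAULT_WAVELENGTHS_NM):
        raise ValueError(
            "no sidecar and page count does not match the default four-color scan"
        )
    return ChipImageSet(
        images=images,
        labels=constants.DEFAULT_WAVELENGTHS_NM,
        layout=layout,
        kind="wavelength",
    )
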