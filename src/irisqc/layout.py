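"""Array layouts: grid geometry plus per-position probe annotations.

Two on-disk dialects are supported: a GenePix GAL-compatible reader
(Block/Column/Row/ID/Name records, single block) and a native structured
YAML dialect that additionally carries spotting concentrations and replicate
groups.  Grid positions are 1-based (row, col), matching array-printing
convention; pixel coordinates elsewhere in the package are 0-based with the
origin at the image's top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml


@dataclass(frozen=True)
class SpotAnnotation:
    """What was printed at one grid position."""

    probe: str
    concentration_um: float | None = None
    replicate_group: str | None = None
    is_blank: bool = False

    @property
    def group(self) -> str:
        """Replicate-group key; defaults to the probe name."""
        return self.replicate_group if self.replicate_group is not None else self.probe


BLANK = SpotAnnotation(probe="", is_blank=True)


@dataclass
class ArrayLayout:
    """Rectangular spot grid with probe annotations.

    pitch_um is the center-to-center spacing; spot_diameter_um the expected
    printed spot diameter (default 150 um: drops from an 80 um piezo nozzle
    spread on the polymer coating); pixel_size_um the image scale.
    """

    n_rows: int
    n_cols: int
    pitch_um: float
    spot_diameter_um: float = 150.0
    pixel_size_um: float = 7.5
    probe_map: dict[tuple[int, int], SpotAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 1:
            raise ValueError("layout must contain at least one position")
        if not (self.pitch_um > self.spot_diameter_um > 0):
            raise ValueError("require pitch > spot diameter > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        for row, col in self.probe_map:
            if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
                raise ValueError(f"annotation at ({row}, {col}) outside grid")
        # every grid position annotated; unannotated positions become blanks
        for row in range(1, self.n_rows + 1):
            for col in range(1, self.n_cols + 1):
                self.probe_map.setdefault((row, col), BLANK)

    @property
    def positions(self) -> list[tuple[int, int]]:
        return [
            (r, c) for r in range(1, self.n_rows + 1) for c in range(1, self.n_cols + 1)
        ]

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um

    @property
    def spot_radius_px(self) -> float:
        return 0.5 * self.spot_diameter_um / self.pixel_size_um

    def annotation(self, row: int, col: int) -> SpotAnnotation:
        return self.probe_map[(row, col)]

    def replicate_positions(self, group: str) -> list[tuple[int, int]]:
        return [
            pos
            for pos, ann in sorted(self.probe_map.items())
            if not ann.is_blank and ann.group == group
        ]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for pos in self.positions:
            ann = self.probe_map[pos]
            if not ann.is_blank:
                seen.setdefault(ann.group, None)
        return list(seen)

    # ---- native YAML dialect ----

    def to_dict(self) -> dict:
        spots = []
        for (row, col), ann in sorted(self.probe_map.items()):
            if ann.is_blank:
                continue
            rec: dict = {"row": row, "col": col, "probe": ann.probe}
            if ann.concentration_um is not None:
                rec["concentration_um"] = ann.concentration_um
            if ann.replicate_group is not None:
                rec["replicate_group"] = ann.replicate_group
            spots.append(rec)
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_um": self.pitch_um,
            "spot_diameter_um": self.spot_diameter_um,
            "pixel_size_um": self.pixel_size_um,
            "spots": spots,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayLayout":
        probe_map = {}
        for rec in d.get("spots", []):
            probe_map[(int(rec["row"]), int(rec["col"]))] = SpotAnnotation(
                probe=str(rec["probe"]),
                concentration_um=rec.get("concentration_um"),
                replicate_group=rec.get("replicate_group"),
            )
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch_um=float(d["pitch_um"]),
            spot_diameter_um=float(d.get("spot_diameter_um", 150.0)),
            pixel_size_um=float(d.get("pixel_size_um", 7.5)),
            probe_map=probe_map,
        )

    @classmethod
    def from_yaml(cls, path) -> "ArrayLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def read_gal(
    path,
    pitch_um: float | None = None,
    spot_diameter_um: float = 150.0,
    pixel_size_um: float = 7.5,
) -> ArrayLayout:
    """Read a GenePix GAL file (single block) into an :class:`ArrayLayout`.

    GAL geometry headers (``Block1= x, y, dia, nx, dx, ny, dy``) supply the
    pitch when present; otherwise ``pitch_um`` must be given.  Spots with ID
    or Name ``"-"`` or empty are treated as blanks.
    """
    header_pitch = None
    n_header = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    # ATF-style preamble: find the record header line
    start = None
    for i, line in enumerate(lines):
        cells = [c.strip().strip('"') for c in line.split("\t")]
        if "Block" in cells and "Column" in cells and "Row" in cells:
            start = i
            break
        if cells and cells[0].startswith("Block") and "=" in line:
            geom = line.split("=", 1)[1].split(",")
            if len(geom) >= 7:
                # x, y, spot diameter, n_cols, dx, n_rows, dy (units: um)
                header_pitch = float(geom[4])
                spot_diameter_um = float(geom[2])
        n_header += 1
    if start is None:
        raise ValueError(f"{path}: no GAL record header (Block/Column/Row) found")
    df = pd.read_csv(path, sep="\t", skiprows=start, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for needed in ("Block", "Column", "Row", "ID"):
        if needed not in df.columns:
            raise ValueError(f"{path}: GAL record table missing column {needed!r}")
    if df["Block"].astype(int).nunique() > 1:
        raise ValueError("multi-block GAL layouts are not supported")
    pitch = pitch_um if pitch_um is not None else header_pitch
    if pitch is None:
        raise ValueError("pitch_um not given and no Block geometry header in GAL file")
    probe_map = {}
    for _, rec in df.iterrows():
        row, col = int(rec["Row"]), int(rec["Column"])
        name = str(rec.get("Name", rec["ID"]) or "").strip()
        ident = str(rec["ID"] or "").strip()
        if ident in ("", "-") and name in ("", "-"):
            probe_map[(row, col)] = BLANK
        else:
            probe_map[(row, col)] = SpotAnnotation(probe=name or ident)
    n_rows = max(r for r, _ in probe_map)
    n_cols = max(c for _, c in probe_map)
    return ArrayLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        pitch_um=float(pitch),
        spot_diameter_um=spot_diameter_um,
        pixel_size_um=pixel_size_um,
        probe_map=probe_map,
    )


def write_gal(layout: ArrayLayout, path) -> None:
    """Write the layout as a minimal single-block GAL file."""
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n2\t5\n")
        fh.write(f'"Type=GenePix ArrayList V1.0"\n')
        fh.write(
            f'"Block1= 1000, 1000, {layout.spot_diameter_um:.1f}, '
            f"{layout.n_cols}, {layout.pitch_um:.1f}, "
            f'{layout.n_rows}, {layout.pitch_um:.1f}"\n'
        )
        fh.write("Block\tColumn\tRow\tID\tName\n")
        for (row, col), ann in sorted(layout.probe_map.items()):
            ident = "-" if ann.is_blank else ann.probe
            fh.write(f"1\t{col}\t{row}\t{ident}\t{ident}\n")
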