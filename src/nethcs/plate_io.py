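"""Images, plate layouts, feature tables, and their on-disk conventions.

Conventions used throughout the package:

* Pixel coordinates are 0-based ``(row, column)`` with the origin at the
  top-left corner of the image; all region properties follow this.
* Intensities are kept in native units as stored (no rescaling on read);
  features that need normalized intensity perform their own normalization.
* The plate-layout CSV is the single source of truth for the experimental
  design; images carry only ``well_id``/``field_index``/``time``/``channel``
  tags.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("nuclear", "ros", "tmrm", "secondary")
ROLES = ("negative_control", "positive_control", "test")
STIMULI = ("none", "PMA", "ionomycin")

LAYOUT_COLUMNS = (
    "well_id",
    "role",
    "stimulus",
    "stimulus_conc",
    "compound_id",
    "compound_conc",
    "timepoint_min",
    "replicate",
)


class FormatError(ValueError):
    """An input file violates a structural requirement."""


class LayoutError(ValueError):
    """A plate layout fails validation; message lists every violation."""


@dataclass(frozen=True)
class WellSpec:
    """Experimental design of one well.

    ``stimulus_conc`` is in nM for PMA and µM for ionomycin, matching how
    the stimuli are dosed in the assay (100 nM PMA for 210 min, 5 µM
    ionomycin for 90 min).
    """

    well_id: str
    role: str
    stimulus: str = "none"
    stimulus_conc: float = 0.0
    compound_id: str = ""
    compound_conc: float = 0.0
    timepoint_min: float = 0.0
    replicate: int = 1
    annotations: Mapping[str, object] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty if valid)."""
        problems = []
        wid = self.well_id
        if not (len(wid) >= 2 and wid[0].isalpha() and wid[1:].isdigit()):
            problems.append(f"well_id {wid!r} is not row-letter+column-number")
        if self.role not in ROLES:
            problems.append(f"{wid}: role {self.role!r} not in {ROLES}")
        if self.stimulus not in STIMULI:
            problems.append(f"{wid}: stimulus {self.stimulus!r} not in {STIMULI}")
        if self.stimulus_conc < 0:
            problems.append(f"{wid}: negative stimulus_conc {self.stimulus_conc}")
        if self.compound_conc < 0:
            problems.append(f"{wid}: negative compound_conc {self.compound_conc}")
        if self.timepoint_min < 0:
            problems.append(f"{wid}: negative timepoint_min {self.timepoint_min}")
        if self.replicate < 1:
            problems.append(f"{wid}: replicate {self.replicate} < 1")
        if self.role == "negative_control":
            if self.stimulus != "none":
                problems.append(f"{wid}: negative_control must have stimulus=none")
            if self.compound_id:
                problems.append(f"{wid}: negative_control must have empty compound")
        if self.role == "positive_control":
            if self.stimulus == "none":
                problems.append(f"{wid}: positive_control requires a stimulus")
            if self.compound_id:
                problems.append(f"{wid}: positive_control must have empty compound")
        return problems


@dataclass
class PlateLayout:
    """A validated collection of :class:`WellSpec`, unique by ``well_id``."""

    wells: list[WellSpec]

    def __post_init__(self) -> None:
        problems = []
        seen: set[str] = set()
        for w in self.wells:
            if w.well_id in seen:
                problems.append(f"duplicate well_id {w.well_id!r}")
            seen.add(w.well_id)
            problems.extend(w.validate())
        if problems:
            raise LayoutError("invalid plate layout:\n  " + "\n  ".join(problems))

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells)

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(f"well {well_id!r} not in layout")

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]


@dataclass
class FieldImage:
    """One grayscale image of one microscope field.

    ``pixel_size`` is in µm/pixel. ``time`` is minutes after treatment.
    """

    pixels: np.ndarray
    channel: str
    pixel_size: float
    well_id: str = ""
    field_index: int = 0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(
                f"FieldImage pixels must be 2-D, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise FormatError(
                f"FieldImage must be at least 64x64, got {self.pixels.shape}"
            )
        if self.channel not in CHANNELS:
            raise FormatError(f"unknown channel {self.channel!r}; expected {CHANNELS}")
        if not self.pixel_size > 0:
            raise FormatError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("FieldImage pixels contain non-finite values")
        if np.any(self.pixels < 0):
            raise FormatError("FieldImage pixels contain negative values")
        if self.field_index < 0:
            raise FormatError(f"field_index must be >= 0, got {self.field_index}")
        if self.time < 0:
            raise FormatError(f"time must be >= 0, got {self.time}")


def read_image(
    path: str | Path,
    channel: str,
    *,
    pixel_size: float,
    well_id: str = "",
    field_index: int = 0,
    time: float = 0.0,
) -> list[FieldImage]:
    """Read a grayscale TIFF into :class:`FieldImage` objects.

    Pixels are returned exactly as stored (no rescaling). Multi-plane files
    yield one ``FieldImage`` per plane, with ``field_index`` counting up
    from the given base. Always returns a list, of length 1 for a
    single-plane file.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - report as format error
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        planes = [data]
    elif data.ndim == 3:
        if data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
            raise FormatError(f"{path}: RGB/RGBA images are not supported")
        planes = list(data)
    else:
        raise FormatError(f"{path}: expected 2-D or 3-D grayscale data, got ndim={data.ndim}")
    return [
        FieldImage(
            pixels=p,
            channel=channel,
            pixel_size=pixel_size,
            well_id=well_id,
            field_index=field_index + i,
            time=time,
        )
        for i, p in enumerate(planes)
    ]


def write_image(img: FieldImage | Sequence[FieldImage], path: str | Path) -> None:
    """Write one or more fields to a (multi-plane) grayscale TIFF."""
    imgs = [img] if isinstance(img, FieldImage) else list(img)
    data = np.stack([i.pixels for i in imgs]) if len(imgs) > 1 else imgs[0].pixels
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_layout(path: str | Path) -> PlateLayout:
    """Read and validate a plate-layout CSV.

    Required columns: ``well_id, role, stimulus, stimulus_conc, compound_id,
    compound_conc, timepoint_min, replicate``. Unknown columns are preserved
    as opaque per-well annotations.
    """
    df = pd.read_csv(path, dtype={"well_id": str, "compound_id": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"layout {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in LAYOUT_COLUMNS]
    wells = []
    for _, row in df.iterrows():
        compound = row["compound_id"]
        if pd.isna(compound):
            compound = ""
        wells.append(
            WellSpec(
                well_id=str(row["well_id"]),
                role=str(row["role"]),
                stimulus=str(row["stimulus"]),
                stimulus_conc=float(row["stimulus_conc"]),
                compound_id=str(compound),
                compound_conc=float(row["compound_conc"]),
                timepoint_min=float(row["timepoint_min"]),
                replicate=int(row["replicate"]),
                annotations={c: row[c] for c in extra},
            )
        )
    return PlateLayout(wells)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    """Write a plate layout to CSV (inverse of :func:`read_layout`)."""
    rows = []
    for w in layout:
        rec = {c: getattr(w, c) for c in LAYOUT_COLUMNS}
        rec.update(w.annotations)
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class CellRecord:
    """One nucleus/cell object: mask, location, label, features.

    ``mask`` is a 2-D boolean patch anchored at ``bbox`` = (row0, col0) in
    the parent field; ``centroid`` is (row, col) in field coordinates.
    Ground-truth records from the simulator and segmented objects share
    this container.
    """

    well_id: str
    field_index: int
    object_id: int
    bbox: tuple[int, int]
    mask: np.ndarray
    phenotype: str = ""
    features: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return (float(rows.mean()) + self.bbox[0], float(cols.mean()) + self.bbox[1])

    def pixel_set(self) -> set[tuple[int, int]]:
        r0, c0 = self.bbox
        rows, cols = np.nonzero(self.mask)
        return {(int(r) + r0, int(c) + c0) for r, c in zip(rows, cols)}


# ---------------------------------------------------------------------------
# Cell / well tables

_CELL_ID_COLUMNS = ("well_id", "field_index", "object_id")


def cells_to_frame(cells: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Assemble per-cell records into a DataFrame with a fixed column order.

    Each record is a mapping with identity keys (``well_id``,
    ``field_index``, ``object_id``), optional ``label`` / ``flag`` columns,
    and numeric feature keys. All records must share the same feature set.
    """
    cells = list(cells)
    if not cells:
        return pd.DataFrame(columns=list(_CELL_ID_COLUMNS))
    keysets = {tuple(sorted(c.keys())) for c in cells}
    if len(keysets) > 1:
        raise ValueError("ragged feature sets: records do not share identical keys")
    keys = list(cells[0].keys())
    ordered = [k for k in _CELL_ID_COLUMNS if k in keys]
    ordered += [k for k in keys if k not in ordered]
    return pd.DataFrame(cells, columns=ordered)


def write_cell_table(cells: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write per-cell features to CSV, one row per cell.

    Floats are printed with 8 significant digits so that round-trips agree
    to better than 1e-6 relative.
    """
    cells_to_frame(cells).to_csv(path, index=False, float_format="%.8g")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"well_id": str})


def write_well_table(summaries: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write per-well summaries (counts and phenotype fractions) to CSV."""
    rows = list(summaries)
    if not rows:
        pd.DataFrame(columns=["well_id"]).to_csv(path, index=False)
        return
    keysets = {tuple(sorted(r.keys())) for r in rows}
    if len(keysets) > 1:
        raise ValueError("ragged summary sets: rows do not share identical keys")
    keys = list(rows[0].keys())
    ordered = ["well_id"] + [k for k in keys if k != "well_id"]
    pd.DataFrame(rows, columns=ordered).to_csv(path, index=False, float_format="%.8g")


def read_well_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"well_id": str})


# ---------------------------------------------------------------------------
# Model serialization (JSON)


def save_json(obj: Mapping[str, object], path: str | Path) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return super().default(o)

    Path(path).write_text(json.dumps(obj, indent=2, cls=_Encoder))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
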