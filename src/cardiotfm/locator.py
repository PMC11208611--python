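"""Cell locator: survey segmentation, morphology gating and stage position lists.

A tiled 10x brightfield survey of a micropatterned device is segmented
into candidate single cells; each cell's spread area, aspect ratio and
orientation are measured from its second central moments; cells are
selected with FACS-like inclusive gates (default: aspect ratio 1.5:1 to
12:1 and area 300-3500 µm²); the surviving cells become a stage position
list that can be revisited on later days, with a rigid x-y offset
estimated and removed before re-identifying each cell by mutual nearest
neighbors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_otsu

POSITION_SCHEMA_VERSION = 1


@dataclass
class CellRecord:
    """One candidate cell on the device."""

    cell_id: str
    stage_x_um: float
    stage_y_um: float
    stage_z_um: float = 0.0
    area_um2: float = 0.0
    aspect_ratio: float = 1.0
    orientation_deg: float = 0.0
    tile_id: str = ""
    day: int = 0
    quadrant: str = "none"

    def __post_init__(self) -> None:
        if self.area_um2 < 0:
            raise ValueError("area must be >= 0")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio must be >= 1")


@dataclass(frozen=True)
class GateSpec:
    """Inclusive morphology gates (flow-cytometry style)."""

    ar_min: float = 1.5
    ar_max: float = 12.0
    area_min_um2: float = 300.0
    area_max_um2: float = 3500.0

    def __post_init__(self) -> None:
        if self.ar_min < 1.0:
            raise ValueError("ar_min must be >= 1")
        if not self.area_min_um2 < self.area_max_um2:
            raise ValueError("area_min must be < area_max")


@dataclass
class PositionList:
    """Ordered stage positions with unique labels (µm)."""

    positions: list[tuple[str, float, float, float]]   # (label, x, y, z)
    device: str = ""
    day: int = 0
    px_size: float = 0.0

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.positions]
        if len(labels) != len(set(labels)):
            raise ValueError("position labels must be unique")

    def xy(self) -> np.ndarray:
        return np.array([[p[1], p[2]] for p in self.positions], dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# survey segmentation
# ---------------------------------------------------------------------------

def segment_survey(survey: np.ndarray, px_size: float,
                   tile_origin_um: tuple[float, float] = (0.0, 0.0),
                   tile_id: str = "", day: int = 0,
                   min_area_um2: float = 50.0,
                   flatten_window_px: int = 81) -> list[CellRecord]:
    """Segment a 10x survey tile into candidate cells.

    The slowly varying transmitted-light background is removed with a
    black top-hat (morphological closing with a large square footprint
    minus the image), the residue is thresholded with Otsu's method,
    connected components are measured with second central moments
    (equivalent-ellipse aspect ratio and orientation), and stage
    coordinates are the tile origin plus the centroid.  A saturated or
    blank tile yields an empty list with a warning.  Deterministic.
    """
    img = np.asarray(survey, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("survey tile is uniform (blank or saturated); no cells found")
        return []
    closed = ndimage.grey_closing(img, size=(flatten_window_px, flatten_window_px))
    flattened = closed - img           # cells are darker than background
    thr = threshold_otsu(flattened)
    fg = flattened > thr
    if fg.mean() > 0.5:
        warnings.warn("survey tile looks saturated; no cells found")
        return []
    labels = measure.label(fg)
    records: list[CellRecord] = []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * px_size ** 2
        if area_um2 < min_area_um2:
            continue
        minor = max(prop.axis_minor_length, 1e-9)
        cy, cx = prop.centroid
        records.append(CellRecord(
            cell_id=f"{tile_id or 'tile'}-{len(records):04d}",
            stage_x_um=tile_origin_um[0] + cx * px_size,
            stage_y_um=tile_origin_um[1] + cy * px_size,
            area_um2=float(area_um2),
            aspect_ratio=float(prop.axis_major_length / minor),
            orientation_deg=float(np.rad2deg(prop.orientation)),
            tile_id=tile_id,
            day=day,
        ))
    return records


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------

def apply_gates(records: Sequence[CellRecord], gates: Optional[GateSpec] = None
                ) -> tuple[list[CellRecord], list[CellRecord]]:
    """Partition records into (selected, rejected) with inclusive bounds."""
    if gates is None:
        gates = GateSpec()
    selected, rejected = [], []
    for r in records:
        ok = (gates.ar_min <= r.aspect_ratio <= gates.ar_max
              and gates.area_min_um2 <= r.area_um2 <= gates.area_max_um2)
        (selected if ok else rejected).append(r)
    return selected, rejected


def quadrant_gate(records: Sequence[CellRecord], median_area_um2: float,
                  median_ar: float) -> list[CellRecord]:
    """Assign morphology quadrants against the two median gates.

    Quadrant I: area >= median and AR >= median; II: smaller area, high AR;
    III: both below; IV: large area, low AR.  The >= convention puts records
    exactly on both medians in quadrant I.  Returns new records.
    """
    if median_area_um2 <= 0 or median_ar <= 0:
        raise ValueError("medians must be positive")
    out = []
    for r in records:
        big = r.area_um2 >= median_area_um2
        elong = r.aspect_ratio >= median_ar
        q = "I" if (big and elong) else "II" if elong else "III" if not big else "IV"
        out.append(replace(r, quadrant=q))
    return out


# ---------------------------------------------------------------------------
# position list I/O
# ---------------------------------------------------------------------------

def write_position_list(records_or_list, path: str | Path,
                        device: str = "", day: int = 0, px_size: float = 0.0
                        ) -> PositionList:
    """Write the canonical JSON position-list schema (versioned).

    Accepts either a :class:`PositionList` or a sequence of
    :class:`CellRecord`.  The canonical write -> read round trip is
    lossless.
    """
    if isinstance(records_or_list, PositionList):
        plist = records_or_list
    else:
        plist = PositionList(
            positions=[(r.cell_id, r.stage_x_um, r.stage_y_um, r.stage_z_um)
                       for r in records_or_list],
            device=device, day=day, px_size=px_size)
    doc = {
        "schema_version": POSITION_SCHEMA_VERSION,
        "device": plist.device,
        "day": plist.day,
        "px_size_um": plist.px_size,
        "positions": [
            {"label": lab, "x_um": x, "y_um": y, "z_um": z}
            for lab, x, y, z in plist.positions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
    return plist


def read_position_list(path: str | Path) -> PositionList:
    """Read a canonical position list or import a Micro-Manager `.pos` file.

    The Micro-Manager dialect (a JSON document with a ``POSITIONS`` array
    of per-device stage coordinates, or the ``map``/``StagePositions``
    variant) is imported on a best-effort basis: the 2-axis device supplies
    x/y and a 1-axis device, when present, supplies z.
    """
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed position list {path}: line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}") from exc
    if "positions" in doc:                      # canonical schema
        positions = [(p["label"], float(p["x_um"]), float(p["y_um"]),
                      float(p.get("z_um", 0.0))) for p in doc["positions"]]
        return PositionList(positions=positions, device=doc.get("device", ""),
                            day=int(doc.get("day", 0)),
                            px_size=float(doc.get("px_size_um", 0.0)))
    if "map" in doc:                            # Micro-Manager 2 dialect
        arr = doc["map"].get("StagePositions", {}).get("array", [])
        positions = []
        for i, p in enumerate(arr):
            label = p.get("Label", {}).get("scalar", f"Pos{i}")
            x = y = z = 0.0
            for dev in p.get("DevicePositions", {}).get("array", []):
                vals = dev.get("Position_um", {}).get("array", [])
                if len(vals) == 2:
                    x, y = float(vals[0]), float(vals[1])
                elif len(vals) == 1:
                    z = float(vals[0])
            positions.append((label, x, y, z))
        return PositionList(positions=positions)
    if "POSITIONS" in doc:                      # Micro-Manager 1.4 dialect
        positions = []
        for i, p in enumerate(doc["POSITIONS"]):
            label = p.get("LABEL", f"Pos{i}")
            x = y = z = 0.0
            for dev in p.get("DEVICES", []):
                axes = int(dev.get("AXES", 0))
                if axes == 2:
                    x, y = float(dev.get("X", 0.0)), float(dev.get("Y", 0.0))
                elif axes == 1:
                    z = float(dev.get("X", 0.0))
            positions.append((label, x, y, z))
        return PositionList(positions=positions)
    raise ValueError(f"unrecognized position-list schema in {path}")


# ---------------------------------------------------------------------------
# longitudinal matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]
    offset_um: tuple[float, float]        # rigid shift mapping list A onto list B
    lost: list[str]                       # labels in A without a partner
    new: list[str]                        # labels in B without a partner


def match_longitudinal(list_a: PositionList, list_b: PositionList,
                       tolerance_um: float = 50.0) -> MatchResult:
    """Re-identify the same cells across imaging days.

    A global rigid x-y offset between the two lists is estimated as the
    component-wise median of nearest-neighbor displacement vectors (robust
    to attrition and new detections); after removing it, cells are paired
    by mutual nearest neighbors within ``tolerance_um`` (default 50 µm,
    less than half the 200 µm pattern pitch).  If two candidates lie
    within tolerance of one target the match is ambiguous and all of them
    are dropped with a warning.
    """
    a = list_a.xy()
    b = list_b.xy()
    labels_a = [p[0] for p in list_a.positions]
    labels_b = [p[0] for p in list_b.positions]
    if a.shape[0] == 0 or b.shape[0] == 0:
        return MatchResult([], (0.0, 0.0), labels_a, labels_b)
    tree_b = cKDTree(b)
    _, nn = tree_b.query(a)
    delta = b[nn] - a
    offset = (float(np.median(delta[:, 0])), float(np.median(delta[:, 1])))
    a_shift = a + np.asarray(offset)
    tree_b = cKDTree(b)
    tree_a = cKDTree(a_shift)
    d_ab, nn_ab = tree_b.query(a_shift)
    d_ba, nn_ba = tree_a.query(b)
    # ambiguity: several shifted A-cells within tolerance of one B target
    counts = np.zeros(b.shape[0], dtype=int)
    for i, (d, j) in enumerate(zip(d_ab, nn_ab)):
        if d <= tolerance_um:
            counts[j] += 1
    ambiguous_b = set(np.nonzero(counts > 1)[0])
    if ambiguous_b:
        warnings.warn(f"{len(ambiguous_b)} targets had multiple candidates within "
                      f"{tolerance_um} µm; all contenders dropped")
    pairs = []
    matched_a, matched_b = set(), set()
    for i in range(a.shape[0]):
        j = nn_ab[i]
        if d_ab[i] <= tolerance_um and j not in ambiguous_b and nn_ba[j] == i:
            pairs.append((labels_a[i], labels_b[j]))
            matched_a.add(i)
            matched_b.add(int(j))
    dropped_a = {i for i in range(a.shape[0])
                 if nn_ab[i] in ambiguous_b and d_ab[i] <= tolerance_um}
    lost = [labels_a[i] for i in range(a.shape[0])
            if i not in matched_a and i not in dropped_a]
    lost += [labels_a[i] for i in sorted(dropped_a)]
    new = [labels_b[j] for j in range(b.shape[0]) if j not in matched_b]
    return MatchResult(pairs=pairs, offset_um=offset, lost=lost, new=new)


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """CSV-ready table of cell records."""
    return pd.DataFrame([{
        "cell_id": r.cell_id, "stage_x_um": r.stage_x_um, "stage_y_um": r.stage_y_um,
        "stage_z_um": r.stage_z_um, "area_um2": r.area_um2,
        "aspect_ratio": r.aspect_ratio, "orientation_deg": r.orientation_deg,
        "tile_id": r.tile_id, "day": r.day, "quadrant": r.quadrant,
    } for r in records])
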