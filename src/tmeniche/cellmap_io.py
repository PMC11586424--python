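"""Segmented-cell maps and clinical tables: containers, readers, writers.

The pipeline starts at segmented cells: one row per cell with its region of
interest (ROI), patient, centroid in micrometres, and either an assigned
cell-type label, per-marker intensities, or both.  Coordinates are
continuous micrometres with the origin at each ROI's lower-left corner;
distances between cells are centroid-to-centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

import numpy as np
import pandas as pd

from .panels import OTHER, Panel

Bounds = Tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

REQUIRED_COLUMNS = ("roi_id", "patient_id", "x", "y")
RESPONSE_LEVELS = ("CR", "PR", "SD", "PD")
RESPONDER_LEVELS = ("CR", "PR")


class CellMapError(ValueError):
    """Raised when a cell table or clinical table fails validation."""


@dataclass
class CellMap:
    """A validated collection of segmented cells grouped by ROI and patient.

    Attributes
    ----------
    cells:
        DataFrame with columns ``cell_id, roi_id, patient_id, x, y`` plus
        optionally ``cell_type`` and one column per panel marker.
    panel:
        The marker/type vocabulary the map is validated against.
    roi_bounds:
        ``roi_id -> (xmin, ymin, xmax, ymax)`` in micrometres.  Inferred
        from coordinate extremes when not supplied.
    """

    cells: pd.DataFrame
    panel: Panel
    roi_bounds: Dict[str, Bounds] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = self.cells.reset_index(drop=True)
        if not self.roi_bounds:
            self.roi_bounds = _infer_bounds(self.cells)
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        df = self.cells
        for col in ("cell_id",) + REQUIRED_COLUMNS:
            if col not in df.columns:
                raise CellMapError(f"missing required column {col!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise CellMapError("non-finite cell coordinate encountered")
        has_type = "cell_type" in df.columns and df["cell_type"].notna().all()
        has_markers = len(self.marker_columns) == len(self.panel.markers)
        if not (has_type or has_markers):
            raise CellMapError(
                "each cell needs a cell_type or a full set of marker intensities"
            )
        if "cell_type" in df.columns:
            allowed = set(self.panel.types) | {OTHER}
            bad = set(df["cell_type"].dropna()) - allowed
            if bad:
                raise CellMapError(
                    f"cell_type values outside panel {self.panel.name!r}: {sorted(bad)}"
                )
        roi_patient = df.groupby("roi_id", sort=False)["patient_id"].nunique()
        multi = roi_patient[roi_patient > 1]
        if len(multi):
            raise CellMapError(f"ROIs mapped to multiple patients: {list(multi.index)}")
        for roi, sub in df.groupby("roi_id", sort=False):
            if roi not in self.roi_bounds:
                raise CellMapError(f"no bounds for ROI {roi!r}")
            xmin, ymin, xmax, ymax = self.roi_bounds[roi]
            inside = (
                (sub["x"] >= xmin) & (sub["x"] <= xmax)
                & (sub["y"] >= ymin) & (sub["y"] <= ymax)
            )
            if not inside.all():
                raise CellMapError(f"cells outside declared bounds in ROI {roi!r}")

    # -- accessors ----------------------------------------------------
    @property
    def marker_columns(self) -> Tuple[str, ...]:
        return tuple(m for m in self.panel.markers if m in self.cells.columns)

    @property
    def roi_ids(self) -> Tuple[str, ...]:
        return tuple(pd.unique(self.cells["roi_id"]))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def roi_patient(self) -> pd.Series:
        """Series mapping roi_id -> patient_id."""
        return self.cells.groupby("roi_id", sort=False)["patient_id"].first()

    def roi_area_mm2(self, roi_id: str) -> float:
        xmin, ymin, xmax, ymax = self.roi_bounds[roi_id]
        return (xmax - xmin) * (ymax - ymin) / 1e6

    def iter_rois(self) -> Iterator[Tuple[str, pd.DataFrame]]:
        yield from self.cells.groupby("roi_id", sort=False)

    def with_types(self, cell_types: pd.Series) -> "CellMap":
        """Return a copy with the ``cell_type`` column replaced."""
        cells = self.cells.copy()
        cells["cell_type"] = cell_types.to_numpy()
        return CellMap(cells, self.panel, dict(self.roi_bounds))


def _infer_bounds(df: pd.DataFrame) -> Dict[str, Bounds]:
    out: Dict[str, Bounds] = {}
    for roi, sub in df.groupby("roi_id", sort=False):
        out[roi] = (
            float(sub["x"].min()), float(sub["y"].min()),
            float(sub["x"].max()), float(sub["y"].max()),
        )
    return out


# ---------------------------------------------------------------------------
# cell-table I/O
# ---------------------------------------------------------------------------

def read_cell_table(
    path: str | Path,
    panel: Panel,
    bounds_path: str | Path | None = None,
    sep: str = ",",
) -> CellMap:
    """Read a delimited cell table into a validated :class:`CellMap`.

    Required columns: ``roi_id, patient_id, x, y``; optional ``cell_id``
    (generated when absent), ``cell_type``, and one column per panel marker.
    ROI bounds are read from ``bounds_path`` when given (falling back to a
    ``<path>.bounds`` sidecar if one exists) and inferred from coordinate
    extremes otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise CellMapError(f"missing required column {col!r} in {path}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            raise CellMapError(f"non-numeric {col!r} coordinate in {path}")
        df[col] = coerced
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    if bounds_path is None:
        default = path.with_suffix(path.suffix + ".bounds")
        bounds_path = default if default.exists() else None
    bounds = read_bounds(bounds_path) if bounds_path else {}
    return CellMap(df, panel, bounds)


def write_cell_table(
    cell_map: CellMap,
    path: str | Path,
    bounds_path: str | Path | None = None,
    sep: str = ",",
) -> Path:
    """Write a cell table (and a ROI-bounds sidecar) as delimited text.

    ``read_cell_table(write_cell_table(m)) == m`` field-for-field; marker
    intensities round-trip at full float precision.
    """
    path = Path(path)
    cols = ["cell_id", "roi_id", "patient_id", "x", "y"]
    if "cell_type" in cell_map.cells.columns:
        cols.append("cell_type")
    cols.extend(cell_map.marker_columns)
    cell_map.cells[cols].to_csv(path, sep=sep, index=False, float_format="%.17g")
    if bounds_path is None:
        bounds_path = path.with_suffix(path.suffix + ".bounds")
    write_bounds(cell_map.roi_bounds, bounds_path)
    return path


def read_bounds(path: str | Path) -> Dict[str, Bounds]:
    """Read a key-value ROI-bounds sidecar (``roi xmin ymin xmax ymax``)."""
    out: Dict[str, Bounds] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        roi, *vals = line.split()
        if len(vals) != 4:
            raise CellMapError(f"malformed bounds line: {line!r}")
        out[roi] = tuple(float(v) for v in vals)  # type: ignore[assignment]
    return out


def write_bounds(bounds: Dict[str, Bounds], path: str | Path) -> Path:
    path = Path(path)
    lines = ["# roi_id xmin ymin xmax ymax"]
    for roi, (xmin, ymin, xmax, ymax) in bounds.items():
        lines.append(f"{roi} {xmin:.17g} {ymin:.17g} {xmax:.17g} {ymax:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = (
    "patient_id", "best_response", "responder",
    "os_months", "os_event", "pfs_months", "pfs_event",
    "ca199_baseline", "ca199_nadir",
)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-patient clinical table and derive ``responder``.

    A responder is a patient whose best overall response is CR or PR.
    Times must be non-negative; CA19-9 columns may be absent or NaN
    (non-evaluable patients).
    """
    df = df.copy()
    if "patient_id" not in df.columns:
        raise CellMapError("clinical table needs a patient_id column")
    if df["patient_id"].duplicated().any():
        raise CellMapError("duplicate patient_id in clinical table")
    if "best_response" in df.columns:
        bad = set(df["best_response"].dropna()) - set(RESPONSE_LEVELS)
        if bad:
            raise CellMapError(f"unknown best_response values: {sorted(bad)}")
        derived = df["best_response"].isin(RESPONDER_LEVELS)
        if "responder" in df.columns:
            if not (df["responder"].astype(bool) == derived).all():
                raise CellMapError("responder flag inconsistent with best_response")
        df["responder"] = derived
    for col in ("os_months", "pfs_months"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise CellMapError(f"negative survival time in {col!r}")
    for col in ("ca199_baseline", "ca199_nadir"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise CellMapError(f"negative concentration in {col!r}")
    return df


def read_clinical_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path, sep=sep))


def write_clinical_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    validate_clinical(df).to_csv(path, sep=sep, index=False)
    return path
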