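"""Cell-type assignment from marker intensities and hotspot ROI selection.

Lineages are gated by nearest signature: each cell's z-scored marker vector
is compared to every lineage's expected-expression row by cosine similarity
and the best match wins; cells below a similarity floor are labelled
"other".  PD-L1 status (macrophages, tumor cells) is resolved after lineage
by a z-score threshold, and Ki67 positivity is an orthogonal per-cell flag.
Hotspot selection replaces the manual choice of lymphocyte-rich regions
with a deterministic sliding-window maximizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cellmap_io import CellMap
from .panels import OTHER, Panel


def zscore_markers(intensity_table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each marker column over all cells (population SD).

    Columns with zero SD (constant markers) are set to all-zero rather than
    dividing by zero.  Raises on empty input.
    """
    if len(intensity_table) == 0:
        raise ValueError("cannot z-score an empty intensity table")
    values = intensity_table.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population convention (ddof=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (values - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return pd.DataFrame(z, index=intensity_table.index,
                        columns=intensity_table.columns)


@dataclass
class GatingResult:
    """Per-cell lineage assignment with scores and optional truth summary."""

    cell_type: pd.Series     # final labels (post PD-L1 split), incl. "other"
    score: pd.Series         # cosine similarity to the winning signature
    lineage: pd.Series       # pre-split lineage labels

    def accuracy(self, truth: Sequence[str]) -> float:
        truth = np.asarray(truth, dtype=object)
        return float((self.cell_type.to_numpy() == truth).mean())

    def confusion(self, truth: Sequence[str]) -> pd.DataFrame:
        return pd.crosstab(
            pd.Series(np.asarray(truth, dtype=object), name="truth"),
            pd.Series(self.cell_type.to_numpy(), name="assigned"),
        )


def _transform_signature(
    signature: pd.DataFrame,
    marker_stats: Optional[Tuple[pd.Series, pd.Series]],
) -> pd.DataFrame:
    """Map a signature into the cells' standardized space.

    When the raw per-marker mean/SD used to z-score the cells is known, the
    signature rows are pushed through the identical transform so cells and
    signatures live in the same space.  Without stats the signature is
    standardized by its own column moments (equivalent to assuming a
    balanced type mixture).
    """
    if marker_stats is not None:
        mean, sd = marker_stats
        mean = mean.reindex(signature.columns)
        sd = sd.reindex(signature.columns).replace(0.0, 1.0)
        return (signature - mean) / sd
    mean = signature.mean(axis=0)
    sd = signature.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (signature - mean) / sd


def assign_lineage(
    normalized_table: pd.DataFrame,
    panel: Panel,
    similarity_floor: float = 0.3,
    pdl1_threshold: Optional[float] = None,
    marker_stats: Optional[Tuple[pd.Series, pd.Series]] = None,
) -> GatingResult:
    """Assign each cell the lineage whose signature row is nearest.

    ``normalized_table`` holds z-scored intensities with one column per
    panel marker.  Signature rows are mapped into the same standardized
    space (via ``marker_stats``, the raw per-marker mean/SD the table was
    z-scored with; or by self-standardization when stats are unavailable)
    and each cell takes the lineage at minimum Euclidean distance —
    robust, unlike direct cosine matching, to a dominant cell type
    compressing its marker's z-scale.  Exact distance ties break by the
    panel's declared priority order, making assignment deterministic and
    order-independent.

    The reported per-cell score is the cosine similarity between the cell's
    z-vector and the winning transformed signature; cells scoring below
    ``similarity_floor`` are labelled "other".  Lineages with a declared
    PD-L1 split are then resolved into PD-L1+/- types by thresholding the
    z-scored PD-L1 column at ``pdl1_threshold`` (default: the midpoint of
    the split pair's transformed PD-L1 signature values).
    """
    missing = set(panel.markers) - set(normalized_table.columns)
    if missing:
        raise ValueError(f"marker columns missing from table: {sorted(missing)}")

    lineage_sig = panel.lineage_signature()
    t_sig = _transform_signature(lineage_sig, marker_stats)
    gating_markers = list(lineage_sig.columns)
    z = normalized_table[gating_markers].to_numpy(dtype=float)
    sig = t_sig.to_numpy(dtype=float)

    d2 = ((z[:, None, :] - sig[None, :, :]) ** 2).sum(axis=2)

    lineages = list(lineage_sig.index)
    rank = np.array([
        panel.priority.index(l) if l in panel.priority else len(panel.priority)
        for l in lineages
    ])
    best_d2 = d2.min(axis=1)
    # among exact ties for the minimum, take the highest-priority lineage
    tied = d2 <= best_d2[:, None]
    pick = np.where(tied, rank[None, :], np.iinfo(np.int64).max).argmin(axis=1)
    lineage_labels = np.array(lineages, dtype=object)[pick]

    # score: cosine between cell and winning signature, both measured from
    # the centroid of all transformed signatures — keeps the score scale
    # comparable across types even when one type dominates the population
    # and compresses its marker's z-range
    center = sig.mean(axis=0)
    zc = z - center
    sc = sig - center
    z_norm = np.linalg.norm(zc, axis=1)
    s_norm = np.linalg.norm(sc, axis=1)[pick]
    dots = np.einsum("ij,ij->i", zc, sc[pick])
    denom = np.where(z_norm > 0, z_norm, 1.0) * np.where(s_norm > 0, s_norm, 1.0)
    score = dots / denom
    lineage_labels[score < similarity_floor] = OTHER

    final = lineage_labels.copy()
    if panel.pdl1_split and panel.pdl1_marker in normalized_table.columns:
        pdl1_z = normalized_table[panel.pdl1_marker].to_numpy(dtype=float)
        full_t_sig = _transform_signature(panel.signature, marker_stats)
        for lineage, (pos, neg) in panel.pdl1_split.items():
            if pdl1_threshold is None:
                thr = float(
                    full_t_sig.loc[[pos, neg], panel.pdl1_marker].mean()
                )
            else:
                thr = pdl1_threshold
            mask = lineage_labels == lineage
            pdl1_pos = pdl1_z > thr
            final[mask & pdl1_pos] = pos
            final[mask & ~pdl1_pos] = neg

    idx = normalized_table.index
    return GatingResult(
        cell_type=pd.Series(final, index=idx, name="cell_type"),
        score=pd.Series(score, index=idx, name="score"),
        lineage=pd.Series(lineage_labels, index=idx, name="lineage"),
    )


def proliferation_flag(
    normalized_table: pd.DataFrame,
    marker: str = "Ki67",
    threshold: float = 1.0,
) -> pd.Series:
    """Ki67+ proliferation flag: z-scored intensity above ``threshold``."""
    if marker not in normalized_table.columns:
        raise ValueError(f"marker {marker!r} not in table")
    return normalized_table[marker] > threshold


def phenotype_cells(
    cell_map: CellMap,
    similarity_floor: float = 0.3,
    pdl1_threshold: Optional[float] = None,
) -> Tuple[CellMap, GatingResult]:
    """Convenience: z-score a map's intensities, gate, return a typed map."""
    markers = list(cell_map.marker_columns)
    if len(markers) != len(cell_map.panel.markers):
        raise ValueError("cell map lacks full marker intensities")
    raw = cell_map.cells[markers]
    z = zscore_markers(raw)
    stats = (raw.mean(axis=0), raw.std(axis=0, ddof=0))
    result = assign_lineage(
        z, cell_map.panel, similarity_floor=similarity_floor,
        pdl1_threshold=pdl1_threshold, marker_stats=stats,
    )
    return cell_map.with_types(result.cell_type), result


# ---------------------------------------------------------------------------
# hotspot ROI selection
# ---------------------------------------------------------------------------

Window = Tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


def select_hotspot_rois(
    x: np.ndarray,
    y: np.ndarray,
    is_target: np.ndarray,
    bounds: Tuple[float, float, float, float],
    roi_size: Tuple[float, float],
    k: int = 1,
    grid_step: float = 10.0,
) -> List[Tuple[Window, int]]:
    """Greedily pick up to ``k`` non-overlapping windows maximizing target cells.

    Candidate window origins lie on a ``grid_step`` lattice anchored at the
    slide's lower-left corner; a window of ``roi_size`` counts the target
    cells it contains (half-open: ``x0 <= x < x0+w``), and windows are
    selected in descending count order, skipping any that overlap an
    already-selected one.  Returns ``[(window, target_count), ...]``.

    An empty list (with a warning) is returned when no target cells exist;
    a window larger than the slide raises.
    """
    xmin, ymin, xmax, ymax = bounds
    w, h = roi_size
    if w > xmax - xmin or h > ymax - ymin:
        raise ValueError("roi_size exceeds slide bounds")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if not is_target.any():
        warnings.warn("no target cells on slide; returning no hotspots")
        return []

    # bin target cells on the grid, then slide an aligned window by 2-D
    # prefix sums; exact for half-open windows whose span is a whole number
    # of grid cells
    wb = max(int(round(w / grid_step)), 1)
    hb = max(int(round(h / grid_step)), 1)
    nx = int(np.ceil((xmax - xmin) / grid_step))
    ny = int(np.ceil((ymax - ymin) / grid_step))
    ix = np.clip(((x[is_target] - xmin) // grid_step).astype(int), 0, nx - 1)
    iy = np.clip(((y[is_target] - ymin) // grid_step).astype(int), 0, ny - 1)
    hist = np.zeros((nx, ny), dtype=np.int64)
    np.add.at(hist, (ix, iy), 1)
    csum = hist.cumsum(axis=0).cumsum(axis=1)
    padded = np.zeros((nx + 1, ny + 1), dtype=np.int64)
    padded[1:, 1:] = csum
    n_ox = nx - wb + 1
    n_oy = ny - hb + 1
    counts = (
        padded[wb:wb + n_ox, hb:hb + n_oy]
        - padded[:n_ox, hb:hb + n_oy]
        - padded[wb:wb + n_ox, :n_oy]
        + padded[:n_ox, :n_oy]
    )

    order = np.argsort(counts, axis=None)[::-1]
    chosen: List[Tuple[Window, int]] = []
    taken: List[Tuple[int, int]] = []
    for flat in order:
        if len(chosen) == k:
            break
        i, j = np.unravel_index(flat, counts.shape)
        if counts[i, j] == 0 and chosen:
            break
        if any(abs(i - ti) < wb and abs(j - tj) < hb for ti, tj in taken):
            continue
        x0 = xmin + i * grid_step
        y0 = ymin + j * grid_step
        chosen.append(((x0, y0, x0 + w, y0 + h), int(counts[i, j])))
        taken.append((i, j))
    return chosen
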