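"""Distance-threshold cell-cell interaction graphs and intensity matrices.

Two cells interact when their centroids lie strictly closer than a
threshold (default 15 um); edges are undirected, computed within each ROI
(never across ROIs), and counted once per unordered type pair — an A-B edge
adds one to entry (A, B) (mirrored for symmetry) and an A-A edge adds one
to the diagonal, so the sum over unordered pairs equals the edge count.

Interaction intensity for a type pair is its edge count, optionally
normalized per cell (divided by the smaller of the two type counts, with
0/0 -> 0, so that ROI size does not dominate) or per ROI area (mm^2).
A label-permutation null (positions fixed, types shuffled within ROI)
contextualizes raw counts as z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cellmap_io import CellMap
from .niche import compare_group_ratios
from .panels import OTHER

DEFAULT_THRESHOLD = 15.0
NORMALIZATIONS = ("raw", "per_cell", "per_area")


@dataclass
class InteractionGraph:
    """Undirected proximity edges per ROI (strict ``distance < threshold``)."""

    threshold: float
    edges: Dict[str, np.ndarray]  # roi_id -> (m, 2) array of cell row positions

    @property
    def n_edges(self) -> int:
        return sum(len(e) for e in self.edges.values())


def build_interaction_graph(
    cell_map: CellMap, threshold: float = DEFAULT_THRESHOLD
) -> InteractionGraph:
    """All and only cell pairs with centroid distance strictly below threshold.

    KD-tree candidates at ``<= threshold`` are filtered to the strict
    inequality so exact-threshold ties are excluded, matching a brute-force
    O(n^2) construction bit-for-bit.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    edges: Dict[str, np.ndarray] = {}
    for roi, sub in cell_map.cells.groupby("roi_id", sort=False):
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        idx = sub.index.to_numpy()
        if len(pts) < 2:
            edges[roi] = np.empty((0, 2), dtype=np.int64)
            continue
        pairs = cKDTree(pts).query_pairs(r=threshold, output_type="ndarray")
        if len(pairs):
            d2 = ((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2).sum(axis=1)
            pairs = pairs[d2 < threshold**2]
        edges[roi] = idx[pairs] if len(pairs) else np.empty((0, 2), dtype=np.int64)
    return InteractionGraph(threshold=float(threshold), edges=edges)


@dataclass
class InteractionMatrix:
    """Per-ROI symmetric type x type interaction intensities."""

    normalization: str
    matrices: Dict[str, pd.DataFrame]
    types: Tuple[str, ...]

    def pair_table(self, pairs: Optional[Sequence[Tuple[str, str]]] = None) -> pd.DataFrame:
        """Long-to-wide table: one row per ROI, one column per unordered pair.

        Columns are named ``"A|B"`` with A before B in panel type order.
        """
        if pairs is None:
            pairs = list(combinations(self.types, 2))
        cols = {}
        for a, b in pairs:
            name = f"{a}|{b}"
            cols[name] = [self.matrices[r].loc[a, b] for r in self.matrices]
        return pd.DataFrame(cols, index=list(self.matrices))


def interaction_matrix(
    graph: InteractionGraph,
    cell_map: CellMap,
    normalization: str = "per_cell",
) -> InteractionMatrix:
    """Count edges per unordered type pair in every ROI, then normalize."""
    if normalization not in NORMALIZATIONS:
        raise ValueError(
            f"unknown normalization {normalization!r}; use one of {NORMALIZATIONS}"
        )
    cells = cell_map.cells
    if "cell_type" not in cells.columns or cells["cell_type"].isna().any():
        raise ValueError("interaction matrices need typed cells")
    categories = list(cell_map.panel.types) + [OTHER]
    cat_index = {t: i for i, t in enumerate(categories)}
    codes = cells["cell_type"].map(cat_index).to_numpy()
    T = len(categories)

    matrices: Dict[str, pd.DataFrame] = {}
    for roi, sub in cells.groupby("roi_id", sort=False):
        counts = np.zeros((T, T), dtype=float)
        e = graph.edges.get(roi, np.empty((0, 2), dtype=np.int64))
        if len(e):
            a = np.minimum(codes[e[:, 0]], codes[e[:, 1]])
            b = np.maximum(codes[e[:, 0]], codes[e[:, 1]])
            np.add.at(counts, (a, b), 1.0)
            counts = counts + np.triu(counts, k=1).T  # mirror for symmetry
        if normalization == "per_cell":
            n_types = np.bincount(codes[sub.index.to_numpy()], minlength=T)
            denom = np.minimum.outer(n_types, n_types).astype(float)
            counts = np.divide(counts, denom, out=np.zeros_like(counts),
                               where=denom > 0)
        elif normalization == "per_area":
            counts = counts / cell_map.roi_area_mm2(roi)
        matrices[roi] = pd.DataFrame(counts, index=categories, columns=categories)
    return InteractionMatrix(
        normalization=normalization, matrices=matrices, types=tuple(categories)
    )


def compare_interactions(
    matrix: InteractionMatrix,
    groups: Sequence,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    method: str = "mannwhitney",
) -> pd.DataFrame:
    """Two-group comparison of per-ROI pair intensities with BH adjustment.

    ``groups`` aligns with the matrix's ROI order.  Delegates to
    :func:`tmeniche.niche.compare_group_ratios`.
    """
    if pairs is not None:
        for a, b in pairs:
            if a not in matrix.types or b not in matrix.types:
                raise ValueError(f"pair ({a}, {b}) absent from panel types")
    table = matrix.pair_table(pairs)
    return compare_group_ratios(table, groups, method=method, adjust=True)


@dataclass
class PermutationNull:
    observed: InteractionMatrix
    expected: Dict[str, pd.DataFrame]   # per-ROI null means
    sd: Dict[str, pd.DataFrame]
    zscores: Dict[str, pd.DataFrame]
    n_perm: int
    seed: int


def interaction_permutation_null(
    cell_map: CellMap,
    threshold: float = DEFAULT_THRESHOLD,
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationNull:
    """Label-shuffle null: positions fixed, types permuted within each ROI.

    Raw edge counts per type pair are recomputed for ``n_perm`` shuffles;
    the observed matrix is reported as a z-score against the null mean and
    SD (entries with zero null SD get z = 0).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    graph = build_interaction_graph(cell_map, threshold)
    observed = interaction_matrix(graph, cell_map, normalization="raw")
    categories = list(observed.types)
    cat_index = {t: i for i, t in enumerate(categories)}
    codes = cell_map.cells["cell_type"].map(cat_index).to_numpy()
    T = len(categories)

    expected, sd, z = {}, {}, {}
    for roi, sub in cell_map.cells.groupby("roi_id", sort=False):
        idx = sub.index.to_numpy()
        e = graph.edges.get(roi, np.empty((0, 2), dtype=np.int64))
        pos_of = {g: i for i, g in enumerate(idx)}
        e_local = np.array(
            [[pos_of[i], pos_of[j]] for i, j in e], dtype=np.int64
        ).reshape(-1, 2)
        local_codes = codes[idx]
        null = np.zeros((n_perm, T, T))
        for p in range(n_perm):
            perm = rng.permutation(local_codes)
            counts = np.zeros((T, T))
            if len(e_local):
                a = np.minimum(perm[e_local[:, 0]], perm[e_local[:, 1]])
                b = np.maximum(perm[e_local[:, 0]], perm[e_local[:, 1]])
                np.add.at(counts, (a, b), 1.0)
                counts = counts + np.triu(counts, k=1).T
            null[p] = counts
        mu = null.mean(axis=0)
        sigma = null.std(axis=0)
        obs = observed.matrices[roi].to_numpy()
        zs = np.divide(obs - mu, sigma, out=np.zeros_like(mu), where=sigma > 0)
        expected[roi] = pd.DataFrame(mu, index=categories, columns=categories)
        sd[roi] = pd.DataFrame(sigma, index=categories, columns=categories)
        z[roi] = pd.DataFrame(zs, index=categories, columns=categories)
    return PermutationNull(
        observed=observed, expected=expected, sd=sd, zscores=z,
        n_perm=n_perm, seed=seed,
    )
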