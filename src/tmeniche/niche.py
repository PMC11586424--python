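"""Neighborhood composition profiles, immune-niche clustering, comparisons.

Each cell's neighborhood profile is the fraction of every cell type among
its neighbors within a fixed radius (closed ball, centroid distances, index
cell excluded).  K-means over these profiles yields recurrent neighborhood
archetypes — immune niches (INs) — whose per-unit proportions are compared
between clinical groups.  Cells with no neighbor inside the radius carry an
all-zero profile and are kept out of the K-means fit under a reserved
"isolated" pseudo-niche (id -1).

The radius is a free parameter (the default 50 um spans roughly 3-4 cell
diameters); the niche count K defaults to 10.  Fitted niche ids are
relabelled in descending cluster-size order so that numbering is
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .cellmap_io import CellMap
from .panels import OTHER

ISOLATED = -1  # pseudo-niche id for zero-neighbor cells

DEFAULT_RADIUS = 50.0
DEFAULT_K = 10


def neighborhood_profile(cell_map: CellMap, radius: float = DEFAULT_RADIUS) -> pd.DataFrame:
    """Per-cell neighbor-type fractions within ``radius`` um, per ROI.

    Returns a DataFrame aligned to ``cell_map.cells`` with one column per
    panel type (plus "other"), and a ``neighbor_count`` column.  Rows with
    ``neighbor_count == 0`` are all-zero; other rows sum to 1.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    cells = cell_map.cells
    if "cell_type" not in cells.columns or cells["cell_type"].isna().any():
        raise ValueError("neighborhood profiles need typed cells")
    categories = list(cell_map.panel.types) + [OTHER]
    cat_index = {t: i for i, t in enumerate(categories)}
    type_codes = cells["cell_type"].map(cat_index).to_numpy()

    counts = np.zeros((len(cells), len(categories)), dtype=np.int64)
    for _, sub in cells.groupby("roi_id", sort=False):
        idx = sub.index.to_numpy()
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 2:
            continue
        pairs = cKDTree(pts).query_pairs(r=radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        gi = idx[pairs[:, 0]]
        gj = idx[pairs[:, 1]]
        np.add.at(counts, (gi, type_codes[gj]), 1)
        np.add.at(counts, (gj, type_codes[gi]), 1)

    total = counts.sum(axis=1)
    fractions = np.divide(
        counts, total[:, None], out=np.zeros_like(counts, dtype=float),
        where=total[:, None] > 0,
    )
    out = pd.DataFrame(fractions, index=cells.index, columns=categories)
    out["neighbor_count"] = total
    return out


@dataclass
class NicheModel:
    """Fitted immune niches: centroids in composition space + assignments."""

    K: int
    centroids: pd.DataFrame          # K x type-composition, rows = niche ids
    assignments: pd.Series           # per-cell niche id; ISOLATED for no-neighbor
    inertia: float
    seed: int

    @property
    def niche_ids(self) -> Tuple[int, ...]:
        return tuple(range(self.K))


def fit_niches(
    profiles: pd.DataFrame,
    K: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
) -> NicheModel:
    """K-means over neighborhood profiles with deterministic relabeling.

    Zero-neighbor cells are excluded from fitting and assigned the reserved
    ``ISOLATED`` id.  Fitted clusters are renumbered 0..K-1 in descending
    size (ties by original label) and centroids recomputed as the means of
    their members' profiles.
    """
    feature_cols = [c for c in profiles.columns if c != "neighbor_count"]
    fit_mask = profiles["neighbor_count"].to_numpy() > 0
    X = profiles.loc[fit_mask, feature_cols].to_numpy(dtype=float)
    if len(np.unique(X, axis=0)) < K:
        raise ValueError(f"K={K} exceeds the number of distinct profiles")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)

    sizes = np.bincount(raw, minlength=K)
    order = np.lexsort((np.arange(K), -sizes))  # descending size, stable
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    labels = relabel[raw]

    assignments = pd.Series(ISOLATED, index=profiles.index, name="niche", dtype=int)
    assignments.loc[fit_mask] = labels
    centroids = pd.DataFrame(
        [X[labels == k].mean(axis=0) for k in range(K)],
        index=range(K), columns=feature_cols,
    )
    return NicheModel(
        K=K, centroids=centroids, assignments=assignments,
        inertia=float(km.inertia_), seed=seed,
    )


def niche_ratios(
    model: NicheModel,
    cell_map: CellMap,
    unit: str = "roi",
) -> pd.DataFrame:
    """Per-unit niche proportion matrix (rows sum to 1).

    ``unit`` is "roi" or "patient".  Isolated cells are excluded from the
    denominator; a unit consisting only of isolated cells is dropped.
    """
    if unit not in ("roi", "patient"):
        raise ValueError(f"unknown unit {unit!r}; use 'roi' or 'patient'")
    key = "roi_id" if unit == "roi" else "patient_id"
    df = pd.DataFrame(
        {key: cell_map.cells[key], "niche": model.assignments}
    )
    df = df[df["niche"] != ISOLATED]
    counts = (
        df.groupby([key, "niche"], sort=False).size().unstack(fill_value=0)
        .reindex(columns=range(model.K), fill_value=0)
    )
    ratios = counts.div(counts.sum(axis=1), axis=0)
    ratios.columns = [f"IN-{k}" for k in ratios.columns]
    return ratios


def compare_group_ratios(
    values: pd.DataFrame,
    groups: Sequence,
    method: str = "mannwhitney",
    adjust: bool = True,
) -> pd.DataFrame:
    """Two-group comparison of each column of ``values``.

    ``method`` is "mannwhitney" (two-sided Mann-Whitney U, default) or
    "welch" (Welch two-sample t).  Returns one row per variable with the
    statistic, two-sided p, group means and their difference (group A minus
    group B, groups in sorted label order), and Benjamini-Hochberg adjusted
    p-values when ``adjust``.
    """
    groups = pd.Series(np.asarray(groups), index=values.index)
    levels = sorted(pd.unique(groups), key=str)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a_mask = (groups == levels[0]).to_numpy()
    b_mask = (groups == levels[1]).to_numpy()
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each group needs at least 2 units")

    rows = []
    for col in values.columns:
        a = values[col].to_numpy(dtype=float)[a_mask]
        b = values[col].to_numpy(dtype=float)[b_mask]
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        elif method == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        elif method == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "variable": col,
                "statistic": stat,
                "pvalue": min(p, 1.0) if np.isfinite(p) else 1.0,
                f"mean_{levels[0]}": float(a.mean()),
                f"mean_{levels[1]}": float(b.mean()),
                "difference": float(a.mean() - b.mean()),
            }
        )
    out = pd.DataFrame(rows).set_index("variable")
    if adjust:
        out["p_adjusted"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def cluster_units_by_niches(
    ratio_table: pd.DataFrame,
    k: Optional[int] = None,
    method: str = "ward",
) -> dict:
    """Agglomerative clustering of units on their niche-ratio vectors.

    Ward linkage on Euclidean distances by default.  Rows are sorted by
    unit id before linkage so the result is invariant to input row order;
    remaining ties break by scipy's deterministic convention.  Returns the
    linkage matrix, the leaf order (unit ids), and, when ``k`` is given,
    flat cluster labels from cutting the dendrogram at ``k`` clusters.
    """
    if len(ratio_table) < 2:
        raise ValueError("clustering needs at least 2 units")
    table = ratio_table.sort_index(kind="stable")
    Z = hierarchy.linkage(table.to_numpy(dtype=float), method=method)
    leaves = [table.index[i] for i in hierarchy.leaves_list(Z)]
    out = {"linkage": Z, "leaf_order": leaves, "units": list(table.index)}
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        out["clusters"] = pd.Series(flat, index=table.index, name="cluster")
    return out
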