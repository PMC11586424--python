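"""End-to-end orchestration: config, run directories, manifests.

A run executes phenotyping (when intensities are present), niche discovery,
interaction quantification, feature assembly, response/survival modelling,
and clinical summaries, writing every intermediate artifact plus a manifest
(config, seed, package version) sufficient to reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .cellmap_io import CellMap, write_cell_table
from .interactions import (
    build_interaction_graph,
    compare_interactions,
    interaction_matrix,
)
from .niche import (
    cluster_units_by_niches,
    compare_group_ratios,
    fit_niches,
    neighborhood_profile,
    niche_ratios,
)
from .phenotyping import phenotype_cells
from .response_model import (
    assemble_features,
    boruta_select,
    feature_columns,
    fit_response_model,
    fit_survival_class_model,
)
from .clinical import ca199_decline, km_estimate, summarize_response

log = logging.getLogger("tmeniche")


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration for a full pipeline run.

    Defaults follow the profiled study where it states a value: 15 um
    interaction threshold, K = 10 niches, 75/25 train/test split, Boruta
    alpha 0.01.  The 50 um neighborhood radius and per-cell interaction
    normalization are package choices surfaced here.
    """

    seed: int = 0
    radius: float = 50.0
    interaction_threshold: float = 15.0
    K: int = 10
    split_fraction: float = 0.75
    n_repeats: int = 100
    boruta_alpha: float = 0.01
    boruta_max_iter: int = 30
    boruta_trees: int = 500
    normalization: str = "per_cell"
    similarity_floor: float = 0.3
    panel: str = "clinical-7"
    os_cutoff: Optional[float] = None   # months; None skips OS model
    pfs_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("radius", "interaction_threshold", "K", "n_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def run_pipeline(
    config: RunConfig,
    cell_map: CellMap,
    clinical: Optional[pd.DataFrame],
    out_dir: str | Path,
) -> Path:
    """Execute the full workflow into ``out_dir``; returns the directory.

    Any stage failure aborts with a stage-tagged error.  Omitting the
    clinical table skips group comparisons, modelling, and clinical
    summaries with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        # -- phenotyping ------------------------------------------------
        stage = "phenotype"
        if len(cell_map.marker_columns) == len(cell_map.panel.markers):
            log.info("gating %d cells from marker intensities", cell_map.n_cells)
            cell_map, _ = phenotype_cells(
                cell_map, similarity_floor=config.similarity_floor
            )
        write_cell_table(cell_map, out / "cells.csv")

        # -- niches ------------------------------------------------------
        stage = "niches"
        profiles = neighborhood_profile(cell_map, radius=config.radius)
        model = fit_niches(profiles, K=config.K, seed=config.seed)
        ratios = niche_ratios(model, cell_map, unit="roi")
        ratios.to_csv(out / "niche_ratios.csv")
        model.centroids.to_csv(out / "niche_centroids.csv")
        assigned = cell_map.cells[["cell_id", "roi_id"]].copy()
        assigned["niche"] = model.assignments.to_numpy()
        assigned.to_csv(out / "niche_assignments.csv", index=False)

        # -- interactions ------------------------------------------------
        stage = "interactions"
        graph = build_interaction_graph(cell_map, config.interaction_threshold)
        matrix = interaction_matrix(graph, cell_map, config.normalization)
        long = []
        for roi, m in matrix.matrices.items():
            stacked = m.stack()
            for (a, b), v in stacked.items():
                long.append({"roi_id": roi, "type_a": a, "type_b": b, "value": v})
        pd.DataFrame(long).to_csv(out / "interactions.csv", index=False)

        # -- features ----------------------------------------------------
        stage = "features"
        features = assemble_features(cell_map, matrix)
        features.to_csv(out / "features.csv")

        if clinical is None:
            warnings.warn("no clinical table: skipping comparisons and models")
            log.warning("clinical stage skipped (no table)")
        else:
            stage = "group-comparisons"
            resp = clinical.set_index("patient_id")["responder"]
            roi_groups = cell_map.roi_patient().map(resp)
            groups = roi_groups.reindex(ratios.index)
            compare_group_ratios(ratios, groups).to_csv(
                out / "niche_comparison.csv"
            )
            compare_interactions(
                matrix, roi_groups.reindex(list(matrix.matrices))
            ).to_csv(out / "interaction_comparison.csv")
            cluster = cluster_units_by_niches(ratios, k=2)
            cluster["clusters"].to_csv(out / "niche_clusters.csv")

            stage = "response-model"
            labels = features["patient_id"].map(resp).astype(int)
            X = features[feature_columns(features)]
            result = fit_response_model(
                X, labels, groups=features["patient_id"],
                split_fraction=config.split_fraction,
                n_repeats=config.n_repeats, seed=config.seed,
            )
            pd.DataFrame({"auc": result.auc_values}).to_csv(
                out / "response_auc.csv", index=False
            )
            result.coefficients.to_csv(out / "response_coefficients.csv")
            boruta = boruta_select(
                X, labels, alpha=config.boruta_alpha,
                max_iter=config.boruta_max_iter, seed=config.seed,
                n_estimators=config.boruta_trees,
            )
            pd.DataFrame(
                {
                    "decision": boruta.decision,
                    "hits": boruta.hits,
                    "pvalue": boruta.pvalue,
                }
            ).to_csv(out / "boruta.csv")

            stage = "survival-models"
            for endpoint, cutoff in (
                ("os", config.os_cutoff), ("pfs", config.pfs_cutoff)
            ):
                if cutoff is None:
                    continue
                clin = clinical.set_index("patient_id")
                t = features["patient_id"].map(clin[f"{endpoint}_months"])
                e = features["patient_id"].map(clin[f"{endpoint}_event"])
                res = fit_survival_class_model(
                    X, t, e, cutoff, groups=features["patient_id"],
                    split_fraction=config.split_fraction,
                    n_repeats=config.n_repeats, seed=config.seed,
                )
                pd.DataFrame({"auc": res.auc_values}).to_csv(
                    out / f"{endpoint}_auc.csv", index=False
                )

            stage = "clinical-summary"
            summary = summarize_response(clinical["best_response"])
            decline = ca199_decline(clinical)
            km_os = km_estimate(
                clinical["os_months"], clinical["os_event"], landmarks=(12.0,)
            )
            (out / "clinical_summary.json").write_text(
                json.dumps(
                    {
                        "n": summary.n,
                        "counts": dict(summary.counts),
                        "orr_percent": summary.orr_percent,
                        "dcr_percent": summary.dcr_percent,
                        "ca199": {
                            "n_evaluable": decline.n_evaluable,
                            "percents": {
                                str(k): v for k, v in decline.percents.items()
                            },
                        },
                        "median_os_months": km_os.median,
                        "os_12m_rate": km_os.landmark_survival.get(12.0),
                    },
                    indent=2,
                )
            )

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "version": __version__,
            "n_cells": int(cell_map.n_cells),
            "n_rois": len(cell_map.roi_ids),
            "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:  # add stage context, then re-raise
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
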