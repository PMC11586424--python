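"""Synthetic cohorts with planted spatial and clinical structure.

Each region of interest (ROI) is a homogeneous Poisson background of cells
(tumor-dominated, emulating a carcinoma field) plus isotropic Gaussian
"blobs" of co-clustered cells whose member types are drawn from a niche
composition.  Two default niche archetypes are planted:

* a dendritic-cell / T-cell niche (DC, CTL, Th plus macrophages) whose blob
  frequency is multiplied by ``effect_size`` in responders, and
* an immunosuppressive stromal niche enriched in non-responders
  (fibroblast-dominated on the 16-type discovery panel; tumor / PD-L1+
  macrophage-dominated on the 7-type clinical panel, which carries no
  fibroblast marker).

Survival times are exponential with a class-specific rate (planted hazard
ratio between responders and non-responders) under independent uniform
administrative censoring, the simplest model sufficient to exercise
Kaplan-Meier and log-rank machinery downstream.

Reproducibility: a single integer seed drives ``numpy.random.SeedSequence``
spawning, in documented order, one child stream per concern (cell placement,
marker intensities, clinical outcomes), so sub-streams are independently
reproducible across platforms (PCG64 generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cellmap_io import Bounds, CellMap
from .panels import Panel, clinical_panel

DEFAULT_BOUNDS: Bounds = (0.0, 0.0, 1000.0, 1000.0)  # 1 mm^2 ROI


@dataclass(frozen=True)
class NicheSpec:
    """One planted multi-cellular niche archetype.

    ``composition`` is a probability vector over cell types (sums to 1);
    ``blob_radius`` is the Gaussian SD of member displacement in um;
    ``cells_per_blob`` the expected member count.
    """

    name: str
    composition: Mapping[str, float]
    blob_radius: float = 30.0
    cells_per_blob: int = 100

    def __post_init__(self) -> None:
        probs = np.asarray(list(self.composition.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"composition of {self.name!r} must be non-negative and sum to 1"
            )
        if self.blob_radius <= 0 or self.cells_per_blob <= 0:
            raise ValueError("blob_radius and cells_per_blob must be positive")


def default_niche_specs(panel: Panel) -> Dict[str, NicheSpec]:
    """Planted niche archetypes appropriate for ``panel``'s vocabulary."""
    if "Fb" in panel.types:  # discovery panel: genuine fibroblast niche
        return {
            "dc_t": NicheSpec(
                "dc_t", {"DC": 0.30, "CTL": 0.25, "Th": 0.25, "M1": 0.20}
            ),
            "stromal": NicheSpec(
                "stromal", {"Fb": 0.60, "FAP+CAF": 0.15, "CTL": 0.10, "Plasma": 0.15}
            ),
        }
    return {
        "dc_t": NicheSpec(
            "dc_t", {"DC": 0.30, "CTL": 0.25, "Th": 0.25, "PDL1-M": 0.20}
        ),
        "stromal": NicheSpec(
            "stromal", {"PDL1+M": 0.50, "Tumor": 0.30, "B": 0.20}
        ),
    }


def default_background_composition(panel: Panel) -> Dict[str, float]:
    """Tumor-dominated background field with sparse immune infiltrate."""
    if "Fb" in panel.types:
        return {
            "PDL1-TC": 0.55, "PDL1+TC": 0.10, "Fb": 0.15, "CTL": 0.05,
            "Th": 0.05, "M1": 0.04, "Monocyte": 0.03, "B": 0.03,
        }
    return {
        "Tumor": 0.75, "CTL": 0.06, "Th": 0.06, "B": 0.04,
        "PDL1+M": 0.03, "PDL1-M": 0.04, "DC": 0.02,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults emulate the profiled trial cohort: 47 patients with tissue
    (about one third responders), 1-3 CTL-hotspot ROIs each, 1 mm^2 ROIs at
    a background density giving roughly 2,000-2,500 cells per ROI.
    ``effect_size`` multiplies the DC/T-cell niche blob frequency in
    responders (1.0 is the null); ``niche_rates_nonresponder`` are Poisson
    means of blob counts per ROI.
    """

    n_responders: int = 16
    n_nonresponders: int = 31
    rois_per_patient: Tuple[int, int] = (1, 3)
    background_density: float = 2000.0  # cells per mm^2
    bounds: Bounds = DEFAULT_BOUNDS
    effect_size: float = 4.0
    niche_rates_nonresponder: Mapping[str, float] = field(
        default_factory=lambda: {"dc_t": 0.8, "stromal": 2.5}
    )
    niche_rates_responder: Optional[Mapping[str, float]] = None
    noise_sd: float = 0.5
    hazard_ratio: float = 0.5  # responder vs non-responder hazard
    median_os_nonresponder: float = 7.0   # months
    median_pfs_nonresponder: float = 4.5  # months
    censor_window: Tuple[float, float] = (6.0, 24.0)  # admin censoring, months
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders <= 0 or self.n_nonresponders <= 0:
            raise ValueError("patient counts must be positive")
        if self.effect_size < 1.0:
            raise ValueError("effect_size >= 1 (1.0 is the null)")
        lo, hi = self.rois_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("rois_per_patient must be an increasing range >= 1")

    def responder_rates(self) -> Dict[str, float]:
        if self.niche_rates_responder is not None:
            return dict(self.niche_rates_responder)
        rates = dict(self.niche_rates_nonresponder)
        rates["dc_t"] = rates.get("dc_t", 0.0) * self.effect_size
        return rates


# ---------------------------------------------------------------------------
# single-ROI simulation
# ---------------------------------------------------------------------------

def simulate_cell_map(
    blobs: Sequence[NicheSpec],
    background_density: float,
    bounds: Bounds = DEFAULT_BOUNDS,
    seed: int | np.random.Generator = 0,
    background_composition: Optional[Mapping[str, float]] = None,
    panel: Optional[Panel] = None,
    roi_id: str = "roi0",
    patient_id: str = "p0",
) -> Tuple[CellMap, pd.DataFrame]:
    """Simulate one ROI: Poisson background plus one blob per entry of ``blobs``.

    Returns the :class:`CellMap` and a ground-truth frame aligned to it with
    columns ``blob`` (blob index, -1 for background) and ``niche`` (niche
    name, "background" for background cells).
    """
    if background_density < 0:
        raise ValueError("background_density must be non-negative")
    xmin, ymin, xmax, ymax = bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate ROI bounds")
    panel = panel or clinical_panel()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    comp = background_composition or default_background_composition(panel)

    area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n_bg = rng.poisson(background_density * area_mm2)
    xs = [rng.uniform(xmin, xmax, n_bg)]
    ys = [rng.uniform(ymin, ymax, n_bg)]
    bg_types = rng.choice(list(comp), size=n_bg, p=list(comp.values()))
    types = [bg_types]
    blob_ids = [np.full(n_bg, -1)]
    niches = [np.full(n_bg, "background", dtype=object)]

    for b, spec in enumerate(blobs):
        missing = set(spec.composition) - set(panel.types)
        if missing:
            raise ValueError(f"niche {spec.name!r} uses unknown types {missing}")
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        n = rng.poisson(spec.cells_per_blob)
        bx = np.clip(rng.normal(cx, spec.blob_radius, n), xmin, xmax)
        by = np.clip(rng.normal(cy, spec.blob_radius, n), ymin, ymax)
        bt = rng.choice(
            list(spec.composition), size=n, p=list(spec.composition.values())
        )
        xs.append(bx)
        ys.append(by)
        types.append(bt)
        blob_ids.append(np.full(n, b))
        niches.append(np.full(n, spec.name, dtype=object))

    n_total = sum(len(a) for a in xs)
    cells = pd.DataFrame(
        {
            "cell_id": [f"{roi_id}_c{i}" for i in range(n_total)],
            "roi_id": roi_id,
            "patient_id": patient_id,
            "x": np.concatenate(xs),
            "y": np.concatenate(ys),
            "cell_type": np.concatenate(types),
        }
    )
    truth = pd.DataFrame(
        {"blob": np.concatenate(blob_ids), "niche": np.concatenate(niches)}
    )
    cell_map = CellMap(cells, panel, {roi_id: bounds})
    return cell_map, truth


def simulate_marker_intensities(
    cell_map: CellMap,
    panel: Optional[Panel] = None,
    noise_sd: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> CellMap:
    """Attach marker intensities: type signature row + N(0, sd), floored at 0."""
    panel = panel or cell_map.panel
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    types = cell_map.cells["cell_type"]
    unknown = set(types) - set(panel.types)
    if unknown:
        raise ValueError(f"cell types absent from panel: {sorted(unknown)}")
    base = panel.signature.loc[types].to_numpy(dtype=float)
    noise = rng.normal(0.0, noise_sd, base.shape) if noise_sd > 0 else 0.0
    intensities = np.maximum(base + noise, 0.0)
    cells = cell_map.cells.copy()
    cells[list(panel.markers)] = intensities
    return CellMap(cells, panel, dict(cell_map.roi_bounds))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    spec: CohortSpec,
    panel: Optional[Panel] = None,
) -> Tuple[CellMap, pd.DataFrame, Dict]:
    """Simulate a full cohort: cell maps, clinical table, and ground truth.

    Responders receive DC/T-cell niche blobs at ``effect_size`` times the
    non-responder Poisson rate.  Returns ``(cell_map, clinical, truth)``
    where ``truth`` records planted parameters and per-cell blob membership.
    """
    panel = panel or clinical_panel()
    niche_specs = default_niche_specs(panel)
    root = np.random.SeedSequence(spec.seed)
    # documented spawn order: child 0 = placement, child 1 = clinical
    placement_seq, clinical_seq = root.spawn(2)
    placement_rng = np.random.default_rng(placement_seq)
    clinical_rng = np.random.default_rng(clinical_seq)

    labels = [True] * spec.n_responders + [False] * spec.n_nonresponders
    lo, hi = spec.rois_per_patient
    frames, truth_frames = [], []
    for p, responder in enumerate(labels):
        patient_id = f"P{p:03d}"
        rates = spec.responder_rates() if responder else dict(
            spec.niche_rates_nonresponder
        )
        n_rois = int(placement_rng.integers(lo, hi + 1))
        for r in range(n_rois):
            roi_id = f"{patient_id}_roi{r}"
            blobs: list[NicheSpec] = []
            for name, rate in rates.items():
                for _ in range(placement_rng.poisson(rate)):
                    blobs.append(niche_specs[name])
            cm, truth = simulate_cell_map(
                blobs,
                spec.background_density,
                spec.bounds,
                seed=placement_rng,
                panel=panel,
                roi_id=roi_id,
                patient_id=patient_id,
            )
            frames.append(cm.cells)
            truth = truth.copy()
            truth["roi_id"] = roi_id
            truth_frames.append(truth)

    cells = pd.concat(frames, ignore_index=True)
    bounds = {roi: spec.bounds for roi in pd.unique(cells["roi_id"])}
    cell_map = CellMap(cells, panel, bounds)
    cell_truth = pd.concat(truth_frames, ignore_index=True)

    clinical = _simulate_clinical(spec, labels, clinical_rng)
    truth = {
        "effect_size": spec.effect_size,
        "hazard_ratio": spec.hazard_ratio,
        "niche_rates_nonresponder": dict(spec.niche_rates_nonresponder),
        "niche_rates_responder": spec.responder_rates(),
        "niche_specs": {
            k: dict(v.composition) for k, v in niche_specs.items()
        },
        "cells": cell_truth,
    }
    return cell_map, clinical, truth


def _simulate_clinical(
    spec: CohortSpec, labels: Sequence[bool], rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential survival with class hazard ratio; uniform admin censoring."""
    rows = []
    rate_os_nr = math.log(2.0) / spec.median_os_nonresponder
    rate_pfs_nr = math.log(2.0) / spec.median_pfs_nonresponder
    for p, responder in enumerate(labels):
        hr = spec.hazard_ratio if responder else 1.0
        t_os = rng.exponential(1.0 / (rate_os_nr * hr))
        t_pfs = rng.exponential(1.0 / (rate_pfs_nr * hr))
        censor = rng.uniform(*spec.censor_window)
        if responder:
            best = "CR" if rng.random() < 0.05 else "PR"
        else:
            best = "SD" if rng.random() < 0.75 else "PD"
        baseline = float(np.exp(rng.normal(5.5, 1.2)))  # ~ CA19-9 U/mL
        decline = rng.beta(2.0, 1.2) if responder else rng.beta(1.2, 1.8)
        rows.append(
            {
                "patient_id": f"P{p:03d}",
                "best_response": best,
                "responder": responder,
                "os_months": float(min(t_os, censor)),
                "os_event": bool(t_os <= censor),
                "pfs_months": float(min(t_pfs, censor)),
                "pfs_event": bool(t_pfs <= censor),
                "ca199_baseline": baseline,
                "ca199_nadir": float(baseline * (1.0 - decline)),
            }
        )
    return pd.DataFrame(rows)
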