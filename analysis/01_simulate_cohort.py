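"""Simulate the study cohort and summarize what was planted.

Writes the clinical table and a cohort summary to results/cohort/, and the
full cell table (large) to scratch/cohort/.
"""

import json

from tmeniche.cellmap_io import write_cell_table, write_clinical_table

from common import SCRATCH, outdir, study_cohort, study_spec


def main() -> None:
    spec = study_spec()
    cell_map, clinical, truth = study_cohort()
    out = outdir("cohort")

    scratch = SCRATCH / "cohort"
    scratch.mkdir(parents=True, exist_ok=True)
    write_cell_table(cell_map, scratch / "cells.csv")
    write_clinical_table(clinical, out / "clinical.csv")

    per_roi = cell_map.cells.groupby("roi_id").size()
    summary = {
        "n_patients": int(clinical.shape[0]),
        "n_responders": int(clinical["responder"].sum()),
        "n_rois": int(len(cell_map.roi_ids)),
        "n_cells": int(cell_map.n_cells),
        "cells_per_roi_median": float(per_roi.median()),
        "planted_effect_size": spec.effect_size,
        "planted_hazard_ratio": spec.hazard_ratio,
        "niche_rates_responder": truth["niche_rates_responder"],
        "niche_rates_nonresponder": truth["niche_rates_nonresponder"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"cohort: {summary['n_patients']} patients "
          f"({summary['n_responders']} responders), {summary['n_rois']} ROIs, "
          f"{summary['n_cells']} cells "
          f"(median {summary['cells_per_roi_median']:.0f} per ROI)")
    print(f"planted: DC/T niche rate x{spec.effect_size:.0f} in responders, "
          f"survival hazard ratio {spec.hazard_ratio}")
    print(f"cell table -> {scratch / 'cells.csv'}")


if __name__ == "__main__":
    main()
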