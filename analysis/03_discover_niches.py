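"""Discover immune niches and compare their prevalence between groups.

Profiles every cell's 50-um neighborhood, clusters profiles into K = 10
niches (pooled across patients), and compares per-ROI niche ratios between
responders and non-responders.  Also fits K = 3 to score recovery of the
two planted archetypes against ground truth (ARI).  Writes ratios,
centroids and comparisons to results/niches/.
"""

import json

from sklearn.metrics import adjusted_rand_score

from tmeniche.niche import (
    cluster_units_by_niches,
    compare_group_ratios,
    fit_niches,
    neighborhood_profile,
    niche_ratios,
)

from common import SEED, outdir, study_cohort


def main() -> None:
    cell_map, clinical, truth = study_cohort()
    out = outdir("niches")

    profiles = neighborhood_profile(cell_map, radius=50.0)
    model = fit_niches(profiles, K=10, seed=SEED)
    model.centroids.round(4).to_csv(out / "centroids.csv")

    ratios = niche_ratios(model, cell_map, unit="roi")
    ratios.round(4).to_csv(out / "roi_ratios.csv")
    resp = clinical.set_index("patient_id")["responder"]
    groups = cell_map.roi_patient().map(resp).reindex(ratios.index)
    comparison = compare_group_ratios(ratios, groups)
    comparison.round(6).to_csv(out / "group_comparison.csv")

    clusters = cluster_units_by_niches(ratios, k=2)
    clusters["clusters"].to_csv(out / "roi_clusters.csv")

    model3 = fit_niches(profiles, K=3, seed=SEED)
    cells_truth = truth["cells"]
    mask = (cells_truth["blob"] >= 0).to_numpy()
    ari = adjusted_rand_score(
        cells_truth.loc[mask, "niche"],
        model3.assignments.to_numpy()[mask],
    )
    (out / "recovery.json").write_text(json.dumps(
        {"planted_archetype_ari_k3": round(ari, 4)}, indent=2))

    sig = comparison[comparison["p_adjusted"] < 0.05]
    print(f"fit K=10 niches over {cell_map.n_cells} cells; "
          f"{len(sig)} niches differ between groups at FDR 0.05:")
    for name, row in sig.iterrows():
        direction = "responders" if row["difference"] < 0 else "non-responders"
        print(f"  {name}: higher in {direction} "
              f"(adj p = {row['p_adjusted']:.2e})")
    print(f"planted-archetype recovery at K=3: ARI {ari:.3f}")


if __name__ == "__main__":
    main()
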