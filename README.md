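# tmeniche

Spatial analysis of the tumor immune microenvironment (TME) from
multiplexed-imaging cell maps, built around the question a phase Ib/II
pancreatic-cancer immunochemotherapy trial raised: does the spatial
organization of immune cells — not just their abundance — predict who
responds to PD-1 blockade plus chemotherapy?

The package takes tables of segmented cells (one row per cell: ROI,
patient, centroid in μm, marker intensities or a type label) plus a
per-patient clinical table, and implements the full analysis chain:

1. **Phenotyping** — z-scored marker intensities are gated to cell types
   by nearest panel signature, with a PD-L1⁺/PD-L1⁻ split applied after
   lineage; CTL-rich "hotspot" windows can be selected deterministically.
2. **Immune niches (INs)** — each cell's neighborhood profile is the
   fraction of every cell type within a fixed radius *r* (default 50 μm);
   K-means over profiles (default K = 10) yields recurrent multicellular
   niches whose per-ROI proportions are compared between responders and
   non-responders (Mann–Whitney, BH-FDR).
3. **Cell–cell interactions** — cells whose centroids lie strictly within
   15 μm are connected; the interaction intensity of a type pair is its
   edge count, normalized by the smaller type count. A label-permutation
   null (positions fixed) contextualizes raw counts as z-scores.
4. **Response prediction** — per ROI, 7 cell ratios + 7 densities
   (cells/mm²) + 15 non-tumor pair intensities (29 features) feed an
   L1-regularized logistic regression over repeated stratified 75/25
   splits (patient-grouped by default; AUC on held-out data only), plus
   Boruta shadow-feature selection (random forest, binomial test at
   α = 0.01). Survival endpoints are dichotomized at a time cutoff and
   modelled the same way.
5. **Trial statistics** — ORR/DCR summaries, CA19-9 decline
   classification, Kaplan–Meier curves with log-rank tests (via
   lifelines), and an exact Simon two-stage design calculator (optimal
   and minimax, exhaustive binomial search).

Because the trial's imaging and clinical data are not public, a
first-class synthetic-data generator (`tmeniche.synthetic_data`) emulates
the study: ~47 patients × 1–3 ROIs, Poisson background of tumor-dominated
tissue plus Gaussian blobs of co-clustered cells. Two niche archetypes are
planted — a DC–CTL–Th (dendritic cell / T cell) niche whose frequency is
multiplied in responders, and an immunosuppressive stromal niche enriched
in non-responders — together with exponential survival times at a planted
hazard ratio. Every downstream stage can therefore be validated against
ground truth.

## Worked example

```python
from tmeniche.synthetic_data import CohortSpec, simulate_cohort
from tmeniche.niche import neighborhood_profile, fit_niches, niche_ratios, compare_group_ratios
from tmeniche.interactions import build_interaction_graph, interaction_matrix, compare_interactions

cell_map, clinical, truth = simulate_cohort(CohortSpec(seed=0))
graph = build_interaction_graph(cell_map, threshold=15.0)
matrix = interaction_matrix(graph, cell_map, normalization="per_cell")
resp = clinical.set_index("patient_id")["responder"]
groups = cell_map.roi_patient().map(resp).reindex(list(matrix.matrices))
print(compare_interactions(matrix, groups).sort_values("p_adjusted").head(3))
```

On the default 47-patient cohort (87 ROIs, ~212k cells) this prints the
pairs most different between responders (R) and non-responders (NR):

```
           statistic        pvalue  mean_False  mean_True  difference  p_adjusted
variable
Th|PDL1-M      289.0  1.426826e-07    0.321979   0.762342   -0.440364    0.000004
Th|DC          312.0  4.177685e-07    0.513901   1.091208   -0.577306    0.000006
Th|CTL         341.0  1.533052e-06    0.307528   0.693223   -0.385695    0.000014
```

(`mean_False`/`mean_True` are the NR/R group means, so negative
differences mean responder-enriched.) The numbered scripts under
`analysis/` run the whole study — simulation, phenotyping (accuracy 0.963
at stain noise SD 0.5), niche discovery, interaction comparison, response
model (mean AUC 0.857 over 100 patient-grouped splits; Boruta confirms 12
features led by DC/T-cell ratios, densities and their interactions),
survival classifiers, and trial statistics — writing tables under
`results/`:

```sh
cd analysis && python 01_simulate_cohort.py && python 03_discover_niches.py  # etc.
```

A `tmeniche` CLI exposes the same stages (`simulate`, `phenotype`,
`niches`, `interactions`, `model`, `clinical`, `design`, `run`).

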