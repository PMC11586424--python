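import warnings

import numpy as np
import pandas as pd
import pytest

from tmeniche import CellMap, clinical_panel
from tmeniche.interactions import build_interaction_graph, interaction_matrix
from tmeniche.niche import fit_niches, neighborhood_profile
from tmeniche.response_model import assemble_features
from tmeniche.synthetic_data import CohortSpec, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def panel7():
    return clinical_panel()


def make_random_map(seed, n_cells=500, panel=None, bounds=(0.0, 0.0, 500.0, 500.0),
                    roi_id="roi0", patient_id="p0"):
    """Uniform random typed cell map (no spatial structure)."""
    panel = panel or clinical_panel()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = bounds
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n_cells)],
            "roi_id": roi_id,
            "patient_id": patient_id,
            "x": rng.uniform(xmin, xmax, n_cells),
            "y": rng.uniform(ymin, ymax, n_cells),
            "cell_type": rng.choice(panel.types, size=n_cells),
        }
    )
    return CellMap(cells, panel, {roi_id: bounds})


@pytest.fixture(scope="session")
def planted_cohort():
    """The planted-effect study cohort: 20+20 patients, effect size 4.

    Shared across recovery tests; everything derived from it is a pure
    function of this one simulation.
    """
    spec = CohortSpec(n_responders=20, n_nonresponders=20, seed=0)
    cell_map, clinical, truth = simulate_cohort(spec)
    return {"spec": spec, "cell_map": cell_map, "clinical": clinical,
            "truth": truth}


@pytest.fixture(scope="session")
def planted_products(planted_cohort):
    """Profiles, niche fit, interaction matrices and features for the cohort."""
    cm = planted_cohort["cell_map"]
    profiles = neighborhood_profile(cm, radius=50.0)
    niche_model = fit_niches(profiles, K=3, seed=0)
    graph = build_interaction_graph(cm, threshold=15.0)
    matrix = interaction_matrix(graph, cm, normalization="per_cell")
    features = assemble_features(cm, matrix)
    resp = planted_cohort["clinical"].set_index("patient_id")["responder"]
    return {
        "profiles": profiles,
        "niche_model": niche_model,
        "graph": graph,
        "matrix": matrix,
        "features": features,
        "responder_by_patient": resp,
    }
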