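"""Shared study configuration for the analysis scripts.

One synthetic cohort stands in for the profiled trial cohort throughout:
47 patients (16 responders, 31 non-responders), 1-3 CTL-hotspot ROIs each,
with the DC/T-cell niche planted at four times the non-responder rate in
responders.  Every script derives all data from this single seeded
simulation so the numbered analyses compose into one coherent study.
"""

from pathlib import Path

from tmeniche.synthetic_data import CohortSpec, simulate_cohort

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_spec() -> CohortSpec:
    return CohortSpec(seed=SEED)


def study_cohort():
    """(cell_map, clinical, truth) for the default study conditions."""
    return simulate_cohort(study_spec())


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
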