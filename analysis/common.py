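"""Shared cohort + pipeline bundle for the numbered analysis drivers.

Every driver works off the same deterministic synthetic cohort (the default
SimulationConfig) and the same full pipeline run; the bundle is cached in
scratch/ so the drivers can be run independently without recomputing.
"""

import os
import pickle
import warnings

from methmotif import PipelineConfig, run_pipeline
from methmotif.synthdata import SimulationConfig, simulate_all

HERE = os.path.dirname(os.path.abspath(__file__))
ROOT = os.path.dirname(HERE)
RESULTS = os.path.join(ROOT, "results", "analysis")
SCRATCH = os.path.join(ROOT, "scratch")

SEED = 1


def get_cohort():
    path = os.path.join(SCRATCH, f"cohort_seed{SEED}.pkl")
    if os.path.exists(path):
        with open(path, "rb") as fh:
            return pickle.load(fh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = simulate_all(SimulationConfig(seed=SEED))
    os.makedirs(SCRATCH, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(ds, fh)
    return ds


def get_bundle():
    path = os.path.join(SCRATCH, f"bundle_seed{SEED}.pkl")
    if os.path.exists(path):
        with open(path, "rb") as fh:
            return pickle.load(fh)
    cfg = PipelineConfig(simulate=SimulationConfig(seed=SEED), seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(cfg)
    os.makedirs(SCRATCH, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh)
    return bundle


def results_dir():
    os.makedirs(RESULTS, exist_ok=True)
    return RESULTS
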