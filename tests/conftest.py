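import numpy as np
import pandas as pd
import pytest

from cellwise._utils import child_seeds
from cellwise.io import RunConfig
from cellwise.pipeline import estimate_stage, markers_stage, model_ladder, simulate_stage
from cellwise.synthetic import simulate_study


@pytest.fixture(scope="session")
def study50():
    """Default observational study: 50 individuals, two tissue samples each."""
    cfg = RunConfig(seed=1, n_individuals=50)
    comp, panel, bundle, truth, s_sorted = simulate_stage(cfg)
    return {"cfg": cfg, "comp": comp, "panel": panel, "bundle": bundle, "truth": truth,
            "s_sorted": s_sorted}


@pytest.fixture(scope="session")
def study50_markers(study50):
    cfg = study50["cfg"]
    ref_da, dars, peak_gene, marker_sites, meth_marks = markers_stage(
        cfg, study50["panel"], study50["bundle"], study50["s_sorted"]
    )
    return {"ref_da": ref_da, "dars": dars, "peak_gene": peak_gene,
            "marker_sites": marker_sites, "meth_marks": meth_marks}


@pytest.fixture(scope="session")
def study50_estimates(study50, study50_markers):
    return estimate_stage(
        study50["cfg"], study50["panel"], study50["bundle"],
        study50_markers["marker_sites"], study50_markers["meth_marks"],
    )


@pytest.fixture(scope="session")
def study50_replicate(study50):
    """Second measurement-noise realization of the same ground-truth compositions."""
    cfg = study50["cfg"]
    bundle2, _ = simulate_study(
        study50["comp"], study50["panel"], dispersion=cfg.dispersion,
        coverage_mean=cfg.coverage_mean, missing_rate=cfg.missing_rate,
        seed=child_seeds(cfg.seed, 5)[4],
    )
    return bundle2


@pytest.fixture(scope="session")
def confounded_run():
    """Case-control study with severe neuronal loss and 5% genuine DA peaks."""
    cfg = RunConfig(
        seed=1, n_individuals=50, condition_shift=[-1.0, 0, 0, 0, 0],
        da_fraction=0.05,
        models=["none", "shuffled", "ordered_factor", "continuous_true"],
    )
    comp, panel, bundle, truth, s_sorted = simulate_stage(cfg)
    ref_da, dars, peak_gene, marker_sites, meth_marks = markers_stage(cfg, panel, bundle, s_sorted)
    estimates = estimate_stage(cfg, panel, bundle, marker_sites, meth_marks)
    ladder = model_ladder(cfg, bundle, truth, estimates, child_seeds(cfg.seed, 6)[5])
    return {"cfg": cfg, "comp": comp, "panel": panel, "bundle": bundle, "truth": truth,
            "ref_da": ref_da, "marker_sites": marker_sites, "estimates": estimates,
            "ladder": ladder}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
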