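import numpy as np
import pandas as pd
import pytest

from conflictscope import (LandscapeConfig, TruthParams, gen_landscape,
                           gen_villages)


@pytest.fixture(scope="session")
def landscape():
    return gen_landscape(LandscapeConfig(extent=(100.0, 100.0), cell_size=2.0, seed=11))


@pytest.fixture(scope="session")
def villages(landscape):
    return gen_villages(landscape, n_villages=40, seed=12)


@pytest.fixture(scope="session")
def truth():
    return TruthParams()


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One shared small end-to-end run (all stages) reused by several tests."""
    from conflictscope.io import RunConfig, run_pipeline
    outdir = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(
        outdir=str(outdir), seed=5, extent=(120.0, 120.0), cell_size=2.0,
        n_events=228, n_villages=75, n_respondents=900,
        samples_per_chain=400, burn_in=120, n_chains=2, thin=5,
        n_absences=400, cv_reps=2,
    )
    report = run_pipeline(config)
    return config, report, outdir
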