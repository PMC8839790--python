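import numpy as np
import pandas as pd
import pytest

from aquahoney import (
    DEFAULT_PARAMS,
    RunConfig,
    SpectraSet,
    WavelengthGrid,
    cut_range,
    generate_design,
    generate_hmf,
    generate_spectra,
    run_study,
)

#: seed used for all frozen-seed tests of the default study conditions
STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_params():
    return DEFAULT_PARAMS.with_seed(STUDY_SEED)


@pytest.fixture(scope="session")
def study_spectra(study_params):
    """Full 153-sample, 2295-spectrum synthetic study."""
    return generate_spectra(generate_design(), study_params)


@pytest.fixture(scope="session")
def study_spectra_cut(study_spectra):
    """The study spectra on the 1300-1600 nm analysis range."""
    return cut_range(study_spectra, 1300, 1600)


@pytest.fixture(scope="session")
def study_hmf(study_params):
    return generate_hmf(generate_design(), study_params)


@pytest.fixture(scope="session")
def fast_study_report(tmp_path_factory):
    """One full-design study replay on the reduced pretreatment grid,
    shared by the pipeline and acceptance tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = RunConfig(seed=STUDY_SEED, grid_choice="fast", output_dir=str(out),
                    render=False)
    return run_study(cfg)


def toy_spectra(n=12, p=24, seed=0, lo=1300.0, step=3.0):
    """Small random SpectraSet with legal metadata, for unit tests."""
    rng = np.random.default_rng(seed)
    wl = lo + step * np.arange(p)
    X = 0.5 + 0.1 * rng.standard_normal((n, p))
    meta = pd.DataFrame(
        {
            "honey_type": "sunflower",
            "temperature_C": ["CONTROL" if i % 2 == 0 else 40 for i in range(n)],
            "time_min": [0 if i % 2 == 0 else 60 for i in range(n)],
            "replicate": [f"R{1 + i % 3}" for i in range(n)],
            "fill": 1,
            "scan": 1 + (np.arange(n) % 5),
        }
    )
    return SpectraSet(WavelengthGrid(wl), X, meta)
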