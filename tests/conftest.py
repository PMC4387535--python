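import numpy as np
import pytest

import u5mbg as m


@pytest.fixture(scope="session")
def grid25() -> m.RasterGrid:
    return m.RasterGrid(x_origin=3.0, y_origin=4.0, cell_size=0.2,
                        n_rows=25, n_cols=25)


@pytest.fixture(scope="session")
def stack25(grid25) -> m.CovariateStack:
    return m.gen_covariate_stack(grid25, seed=7)


@pytest.fixture(scope="session")
def paper_model() -> m.STGPModel:
    """Generating model at the magnitudes of the motivating survey analysis."""
    return m.STGPModel(
        beta={"intercept": 0.1815, "accessibility": 0.0044, "evi": -0.0045},
        sigma2=7e-4, kappa=np.sqrt(8.0) / 4.5, nugget=2.2e-3, rho=-0.47)


@pytest.fixture(scope="session")
def strong_model() -> m.STGPModel:
    """Well-identified field: strong spatial signal relative to the nugget."""
    return m.STGPModel(beta={"intercept": 0.2, "accessibility": 0.03},
                       sigma2=4e-3, kappa=np.sqrt(8.0) / 2.0,
                       nugget=1e-3, rho=0.0)


@pytest.fixture(scope="session")
def toy_clusters(stack25, strong_model):
    clusters, truth = m.simulate_survey(stack25, strong_model, n_clusters=80,
                                        n_waves=2, seed=11)
    return clusters, truth


@pytest.fixture(scope="session")
def toy_fit(stack25, toy_clusters) -> m.FitResult:
    clusters, _ = toy_clusters
    return m.fit(clusters, stack25, ["accessibility"],
                 m.FitConfig(n_starts=2, seed=5))
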