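import numpy as np
import pytest

import facemorph as fm
from facemorph.synthetic import default_truth


@pytest.fixture(scope="session")
def study_scale_analysis():
    """One full default-condition analysis (5 species x 2 ages x 8 = 80
    specimens, 97 landmarks), shared across tests: GPA + bending-energy
    sliding, tangent projection, relative warps."""
    truth = default_truth(seed=0)
    dataset, truth = fm.simulate_dataset(truth, n_per_cell=8)
    fit = fm.generalized_procrustes(dataset)
    fit = fm.slide_semilandmarks(fit, dataset.sliders, mode="bending_energy")
    rows = fm.tangent_project(fit)
    model = fm.relative_warps(
        rows, consensus=fit.consensus, age_labels=dataset.age_labels()
    )
    return {
        "truth": truth,
        "dataset": dataset,
        "fit": fit,
        "rows": rows,
        "model": model,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def separable_toy(rng):
    """Two well-separated Gaussian clusters with age-class labels."""
    n = 20
    x0 = rng.normal(loc=-3.0, scale=0.3, size=(n, 2))
    x1 = rng.normal(loc=3.0, scale=0.3, size=(n, 2))
    features = np.vstack([x0, x1])
    labels = np.array(["adult"] * n + ["infant"] * n)
    return features, labels
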