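import numpy as np
import pytest

from octdme.errors import EmptyRegionError
from octdme.levelset import (
    EvolutionParams,
    initialize_dme_phi,
    run_sbgfrls,
    run_sbgfrls_oct,
)
from octdme.phantom import PhantomParams, default_suite, generate
from octdme.roi_kmeans import extract_roi, kmeans_intensity


NOISELESS_POCKETS = ((56.0, 70.0, 8.0, 14.0), (52.0, 130.0, 6.0, 10.0))


@pytest.fixture(scope="session")
def noiseless_sample():
    """Separable phantom: three exact intensity levels, no speckle, no blur."""
    return generate(
        PhantomParams(pockets=NOISELESS_POCKETS, speckle_shape=0.0, blur_sigma=0.0)
    )


def run_pipeline(sample, params=None):
    """Stage 1 + Stage 2 on one phantom sample."""
    params = params or EvolutionParams()
    model = kmeans_intensity(sample.image)
    roi = extract_roi(sample.image, model)
    result = run_sbgfrls_oct(sample.image, roi, params)
    return model, roi, result


@pytest.fixture(scope="session")
def speckle_suite_runs():
    """The fixed 20-phantom speckle suite with both segmentation engines run
    from the same initialization and parameters (balloon sign chosen for a
    dark target so the conventional engine addresses the same task)."""
    params = EvolutionParams(alpha=-20.0)
    records = []
    for sample in default_suite(20, 0):
        model = kmeans_intensity(sample.image)
        roi = extract_roi(sample.image, model)
        oct_res = run_sbgfrls_oct(sample.image, roi, params)
        init = initialize_dme_phi(sample.image, roi)
        try:
            base = run_sbgfrls(sample.image, init, params)
            base_iters, base_terminated = base.iterations, True
        except EmptyRegionError as e:
            # single-pixel seed collapsed: the run ended, count its iterations
            base_iters, base_terminated = e.iteration, True
        records.append(
            {
                "sample": sample,
                "roi": roi,
                "oct": oct_res,
                "base_iterations": base_iters,
                "base_terminated": base_terminated,
            }
        )
    return records
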