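import numpy as np
import pandas as pd
import pytest

from dediffquant.imaging import segment_image
from dediffquant.simulate import (
    ExprSimConfig,
    ImageSimConfig,
    generate_expression_matrix,
    generate_tumor_image,
)


@pytest.fixture(scope="session")
def small_scene():
    """50 well-separated cells, default noise; segmentation should be perfect."""
    cfg = ImageSimConfig(n_cells=50, rng_seed=1)
    image, truth = generate_tumor_image(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def small_scene_segmented(small_scene):
    _, image, _ = small_scene
    return segment_image(image)


@pytest.fixture(scope="session")
def expr_default():
    cfg = ExprSimConfig(rng_seed=5)
    counts, groups, truth = generate_expression_matrix(cfg)
    return cfg, counts, groups, truth


def make_records(medians_a, medians_b, genotype="g", tumor="T1", channel_a="tf",
                 channel_b="marker"):
    """Minimal CellRecord frame for two channel/compartment columns."""
    n = len(medians_a)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "tumor_id": [tumor] * n,
            "genotype": [genotype] * n,
            f"{channel_a}_nucleus_median": medians_a,
            f"{channel_b}_cytoplasm_median": medians_b,
        }
    )
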