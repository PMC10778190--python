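import numpy as np
import pandas as pd
import pytest

import sparkmap as sm


@pytest.fixture(scope="session")
def small_cell():
    """A ~4 um cell mask at 0.1 um/px, shared across point-statistics tests."""
    mask = sm.gen_cell_mask((100, 100), 4.0, 0.2, seed=1)
    return mask


@pytest.fixture(scope="session")
def rendered_field(small_cell):
    """Puncta field -> localizations -> rendered map, with truth attached."""
    puncta = sm.gen_puncta_field(small_cell, 13.4, seed=2)
    locs = sm.gen_localizations(puncta, mask=small_cell, false_rate_per_um2=1.0, seed=3)
    rmap = sm.render_delaunay(locs, n_jitter=3, seed=4)
    return {"mask": small_cell, "puncta": puncta, "locs": locs, "map": rmap}


@pytest.fixture(scope="session")
def quiet_movie():
    """Spark-free movie at the default SNR (noise + baseline only)."""
    mask = sm.gen_cell_mask((80, 80), 3.0, 0.1, seed=5)
    params = sm.MovieParams(n_frames=60)
    movie, truth = sm.gen_spark_movie(mask, params=params, rate_per_frame=0.0, seed=6)
    assert len(truth) == 0
    return movie, mask


@pytest.fixture(scope="session")
def csr_points():
    """600 uniform points in a 3 x 3 um box, as a localization table."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "x_nm": rng.uniform(500.0, 3500.0, 600),
            "y_nm": rng.uniform(500.0, 3500.0, 600),
        }
    )
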