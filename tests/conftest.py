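import numpy as np
import pandas as pd
import pytest

from spatmicro.synthetic import scaled_config, simulate_study


def make_cells(coords, taxa, image_id="img1"):
    """Build a CellTable from explicit coordinates and taxon labels."""
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame({
        "image_id": image_id,
        "x_um": coords[:, 0],
        "y_um": coords[:, 1],
        "taxon_id": np.asarray(taxa, dtype=np.int64),
    })


def make_meta(image_ids, tissue="cecum", treatment="water", day=-8,
              mouse_id="m0", fov_um=(135.0, 135.0)):
    return pd.DataFrame({
        "image_id": list(image_ids),
        "mouse_id": mouse_id,
        "tissue": tissue,
        "treatment": treatment,
        "day": day,
        "section": 1,
        "fov": range(1, len(image_ids) + 1),
        "fov_width_um": fov_um[0],
        "fov_height_um": fov_um[1],
    })


@pytest.fixture(scope="session")
def scaled_study():
    """One reduced study with every planted effect, shared across tests."""
    cfg = scaled_config(seed=0)
    cells, meta, truth = simulate_study(cfg)
    return cfg, cells, meta, truth
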