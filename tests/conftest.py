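import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spatialephys import alignment as al
from spatialephys import lfp
from spatialephys import synthetic


def small_params(**overrides):
    """A fast desk-scale slice: 16x16 electrodes, 60 genes, dense spots."""
    defaults = dict(
        rows=16,
        cols=16,
        n_genes=60,
        n_spots=60,
        spot_spacing=80.0,
        duration=120.0,
        coupled_frac=0.1,
        coupling=0.8,
    )
    defaults.update(overrides)
    return synthetic.SliceParams(**defaults)


@pytest.fixture(scope="session")
def small_slice():
    params = small_params()
    return params, synthetic.simulate_multimodal_slice(params, seed=11)


def spot_feature_table(params, table, expr, landmarks):
    """Run the alignment path: electrode features aggregated per spot."""
    feats = lfp.compute_electrode_features(table)
    tf = al.compute_alignment(landmarks)
    fused = al.apply_transform(expr.spot_xy, tf)
    spot_map = al.match_spots_to_electrodes(
        expr.spots,
        fused,
        params.spot_diameter,
        feats.index.tolist(),
        feats[["x_um", "y_um"]].to_numpy(dtype=float),
        pitch=params.pitch,
    )
    return al.aggregate_features_per_spot(spot_map, feats), spot_map, tf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
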