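import numpy as np
import pytest
from hypothesis import settings

import ctrsa

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> ctrsa.PhantomSpec:
    """Tiny phantom for fast unit tests (~150k voxels)."""
    return ctrsa.PhantomSpec(
        bone_length=38.0, bone_outer_radius=10.0, bone_inner_radius=3.6,
        canal_offset_mm=1.0, bone_taper=0.12, soft_radius=15.0,
        plate_extent=(18.0, 14.0, 3.5), stem_length=18.0, stem_radius=2.4,
        stem_offset_mm=1.2,
        spacing=(0.6, 0.6, 0.7), volume_shape=(68, 68, 86),
    )


@pytest.fixture(scope="session")
def small_volume(small_spec) -> ctrsa.Volume:
    return ctrsa.rasterize_scene(small_spec)


@pytest.fixture(scope="session")
def small_labels(small_spec) -> np.ndarray:
    return ctrsa.rasterize_labels(small_spec)


@pytest.fixture(scope="session")
def small_model(small_spec) -> ctrsa.PointSet:
    return ctrsa.implant_point_model(small_spec)


@pytest.fixture(scope="session")
def compact_pair():
    """Noiseless compact-phantom rescan pair with its ground truth."""
    spec = ctrsa.PhantomSpec.compact()
    series = ctrsa.simulate_series(spec, ctrsa.NO_DEGRADATION, n_poses=2, seed=11)
    return spec, series


@pytest.fixture(scope="session")
def compact_prepared(compact_pair):
    """Prepared scan objects (with surfaces) for the compact pair."""
    spec, series = compact_pair
    model = ctrsa.implant_point_model(spec)
    cfg = ctrsa.StudyConfig()
    prepared = [
        ctrsa.prepare_scan(vol, model, cfg, surfaces=True) for vol, _ in series
    ]
    return spec, series, model, cfg, prepared
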