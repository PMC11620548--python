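import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from cmri.grids import GridGeoref, SceneStack


def make_scene(nir, red=None, swir=None, green=None, cloud=None,
               date=dt.date(2020, 3, 15), pixel_size=10.0):
    """Tiny scene builder: scalars broadcast over the NIR grid's shape."""
    nir = np.atleast_2d(np.asarray(nir, dtype=float))
    shape = nir.shape

    def grid(v, default):
        if v is None:
            v = default
        return np.broadcast_to(np.asarray(v, dtype=float), shape).copy()

    return SceneStack(
        red=grid(red, 0.1), green=grid(green, 0.08),
        nir=nir, swir=grid(swir, 0.2),
        cloud_mask=np.zeros(shape, bool) if cloud is None
        else np.broadcast_to(np.asarray(cloud, bool), shape).copy(),
        date=date, georef=GridGeoref(pixel_size=pixel_size))


@pytest.fixture
def scene_factory():
    return make_scene


@pytest.fixture(scope="session")
def noisefree_world():
    """64x64 landscape rendered without noise or clouds, 1 scene/period."""
    from cmri import synthetic

    truth = synthetic.build_landscape(seed=3, shape=(64, 64), patch_scale=6)
    profiles = {k: synthetic.PhenologyProfile(
        k, p.bimonthly_cmri_means, 0.0)
        for k, p in synthetic.default_profiles().items()}
    scenes = synthetic.render_scenes(truth, profiles, years=[2020],
                                     scenes_per_period=1,
                                     cloud_fraction_range=(0.0, 0.0),
                                     seed=5)
    return truth, profiles, scenes
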