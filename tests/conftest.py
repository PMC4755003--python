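import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tilquant.segmentation import NucleusObject, ObjectCatalogue
from tilquant.simulate import _E_VEC, _H_VEC

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_catalogue(points_by_class, mpp=1000.0, phase="pre_treatment", slide_id="s"):
    """Catalogue from {class: [(x, y), ...]} point lists.

    The default mpp of 1000 um/px makes pixel coordinates equal to
    millimetres, so densities can be reasoned about directly.
    """
    objs = []
    oid = 1
    for cls, pts in points_by_class.items():
        for x, y in pts:
            objs.append(
                NucleusObject(oid, slide_id, float(x), float(y), 20, 3.0, 3.0, 0.0,
                              (20.0, math.log10(20), 0.0, 3.0, 0.5, 0.1, 0.1, 0.1), cls)
            )
            oid += 1
    return ObjectCatalogue(slide_id, phase, objs, mpp=mpp)


def od_to_rgb(h_od, e_od):
    """Forward Beer-Lambert rendering used to build hand-made tiles."""
    od_rgb = h_od[:, :, None] * _H_VEC + e_od[:, :, None] * _E_VEC
    return np.clip(np.rint(256.0 * 10.0 ** (-od_rgb) - 1.0), 0, 255).astype(np.uint8)


def stroma_tile(h, w, h_od=0.05, e_od=0.25):
    """Flat pink-stroma OD rasters ready for disc painting."""
    return np.full((h, w), h_od), np.full((h, w), e_od)


def paint_disc(h_arr, cx, cy, r, od):
    yy, xx = np.mgrid[0 : h_arr.shape[0], 0 : h_arr.shape[1]]
    h_arr[np.hypot(xx - cx, yy - cy) <= r] += od


@pytest.fixture(scope="session")
def trained_cloud_model():
    """A small SVM trained on well-separated Gaussian clouds, shared across
    classification tests to avoid refitting the grid search repeatedly."""
    from tilquant.classification import TrainingSet, train_classifier
    from tilquant.simulate import gaussian_clouds

    X, y = gaussian_clouds(120, 10.0, seed=11)
    return train_classifier(TrainingSet(X, y), seed=0), (X, y)
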