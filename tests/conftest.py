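import numpy as np
import pytest

from citruspick.labelio import FRUIT_CLASS, STEM_CLASS, InstanceMask
from citruspick.scenegen import SceneConfig, generate_scene, scene_seed


def make_mask(raster, class_id=FRUIT_CLASS, instance_id=0, confidence=1.0):
    raster = np.asarray(raster, dtype=bool)
    return InstanceMask(
        raster=raster, class_id=class_id, instance_id=instance_id,
        confidence=confidence, empty=not raster.any(),
    )


def disk_mask(shape, cx, cy, r, **kw):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return make_mask((xx - cx) ** 2 + (yy - cy) ** 2 <= r * r, **kw)


def bar_mask(shape, x0, x1, y0, y1, **kw):
    raster = np.zeros(shape, dtype=bool)
    raster[y0 : y1 + 1, x0 : x1 + 1] = True
    return make_mask(raster, class_id=STEM_CLASS, **kw)


@pytest.fixture(scope="session")
def clean_scenes():
    """30 occlusion-free scenes shared by matching/pick-point tests."""
    cfg = dict(n_fruits=3, p_shared_stem=0.25, p_fruitless_stem=0.2)
    return [
        generate_scene(SceneConfig(**cfg, seed=scene_seed(11, i))) for i in range(30)
    ]
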