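import numpy as np
import pytest
from PIL import Image

from thrombostage.io_model import Part, RoiMask, SectionImage, ThrombusSection
from thrombostage.qpia import Palette, WeightingParams


@pytest.fixture
def palette():
    return Palette()


@pytest.fixture
def unweighted():
    """Weighting switched off: every tissue pixel counts 1."""
    return WeightingParams(gamma=0)


@pytest.fixture
def write_png(tmp_path):
    def _write(arr, name="img.png"):
        path = tmp_path / name
        Image.fromarray(arr).save(path)
        return path

    return _write


def make_section(pixels, mask=None, part=Part.HEAD, day=1, animal="a1"):
    pixels = np.asarray(pixels, dtype=np.uint8)
    if mask is None:
        mask = np.ones(pixels.shape[:2], dtype=bool)
    return ThrombusSection(
        animal_id=animal,
        day=day,
        part=part,
        image=SectionImage(pixels=pixels),
        mask=RoiMask(mask=np.asarray(mask, dtype=bool)),
    )


def uniform_section(color, h=8, w=8, **kw):
    px = np.zeros((h, w, 3), dtype=np.uint8)
    px[:] = color
    return make_section(px, **kw)
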