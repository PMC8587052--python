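import numpy as np
import pytest

from quadfluor.synth import IntensityTable, SceneConfig

# Small frames keep unit tests fast; the full 25-circle grid at spacing 56
# spans +/-(158.4 + 22) px about the center, fitting a 400 px frame at any
# rotation angle with room for the camera-aim offsets.
SMALL = dict(image_width=400, image_height=400, rotation_center=(199.5, 199.5),
             grid_spacing=56.0, tube_radius=22.0, background_level=0.0,
             noise_sd=0.0, vignette_strength=0.0, mark_level=200.0)


@pytest.fixture
def make_scene():
    """Factory for small test scenes; kwargs override the small defaults."""
    def _make(angle=25.0, **kw):
        params = {**SMALL, "rotation_angle": angle, **kw}
        return SceneConfig(**params)
    return _make


@pytest.fixture
def uniform_table():
    def _make(value: float, label: str = "") -> IntensityTable:
        return IntensityTable(np.full((5, 5), float(value)), label)
    return _make
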