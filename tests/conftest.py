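import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import paindraw as pdw
from paindraw.model import BodyTemplate, PainDrawing, SymptomLayer

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    """Small synthetic humanoid template used throughout the suite."""
    return pdw.make_template((96, 64))


@pytest.fixture(scope="session")
def toy_template():
    """Single-view 20x20 toy template: full-canvas outline, 19 row bands.

    Every pixel belongs to the outline (400 outline pixels) and rows map to
    regions 1..19 (the last two rows share region 19), so expected values of
    extent / WPI / cluster examples can be counted by hand.
    """
    outline = np.ones((20, 20), dtype=bool)
    labels = np.minimum(np.arange(20) + 1, 19)[:, None] * np.ones((1, 20), dtype=int)
    return BodyTemplate(outline={"front": outline},
                        region_labels={"front": labels.astype(np.int32)})


def make_drawing(template, masks, intensities=None, descriptors=None,
                 subject_id="S001", role="patient"):
    """Build a drawing from a list of per-view mask dicts (one per layer)."""
    n = len(masks)
    intensities = intensities or [7.0] * n
    descriptors = descriptors or ["burning"] * n
    layers = []
    for m, i, d in zip(masks, intensities, descriptors):
        full = {v: np.zeros(template.shape(v), dtype=bool) for v in template.views}
        for view, arr in m.items():
            full[view] = np.asarray(arr, dtype=bool)
        layers.append(SymptomLayer(descriptor=d, intensity=i, masks=full))
    return PainDrawing(subject_id=subject_id, role=role, layers=tuple(layers))


@pytest.fixture
def drawing_factory():
    return make_drawing


@pytest.fixture(scope="session")
def default_cohort(template):
    """One default-condition cohort (n=47) shared by read-only tests."""
    cfg = pdw.SimulationConfig(template_size=(96, 64), seed=20250925)
    _, records = pdw.simulate_cohort(cfg, template=template)
    return records
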