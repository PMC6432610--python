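import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import vidsleep as vs


def make_textured_frame(shape=(96, 128), seed=0, sigma=2.0) -> np.ndarray:
    """A smooth random texture with full 0-255 dynamic range: realistic
    enough for block matching to see gradients."""
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.normal(size=shape), sigma)
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    return (raw * 255).astype(np.uint8)


@pytest.fixture(scope="session")
def textured_frame() -> np.ndarray:
    return make_textured_frame()


@pytest.fixture(scope="session")
def default_cohort():
    """One default 10-subject synthetic cohort, shared across tests."""
    return vs.simulate_cohort(seed=123)


@pytest.fixture(scope="session")
def separable_cohort():
    """Three hand-built subjects whose wake and sleep epochs are linearly
    separable in mACT: every wake epoch carries strong, tightly clustered
    activity and sleep carries none, so the discriminant boundary falls
    cleanly between the classes."""
    rng = np.random.default_rng(42)
    cohort = {}
    for k in range(3):
        labels = []
        while len(labels) < 80:
            labels += ["W"] * int(rng.integers(8, 15))
            labels += ["N2"] * int(rng.integers(20, 30))
        labels = np.array(labels[:80])
        activity = np.zeros(80 * 300)
        for i, lab in enumerate(labels):
            if lab == "W":
                activity[i * 300 : (i + 1) * 300] = 8.0 + (i % 3)
        rec = vs.SyntheticRecording(
            subject_id=f"S{k + 1:02d}",
            hypnogram=labels,
            actigraphy=vs.ActigraphySignal(activity),
        )
        cohort[rec.subject_id] = rec
    return cohort
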