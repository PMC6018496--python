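import numpy as np
import pytest

from kcfbs import synthetic_scene as ss
from kcfbs import tracker


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cameras():
    """A matched orthogonal camera pair for geometry tests."""
    return ss.default_cameras((360, 480))


@pytest.fixture(scope="session")
def occlusion_run():
    """Occlusion scene tracked once with and once without re-detection.

    Session-scoped because rendering plus two tracking passes is the most
    expensive fixture in the suite and several tests inspect it.
    """
    traj, scene = ss.occlusion_scene(seed=5)
    top, side, truth = ss.render_views(traj, scene)
    box = ss.initial_box(truth["top"])
    rec_bs, ev_bs = tracker.track_sequence(top, box, tracker.TrackerConfig())
    rec_kcf, _ = tracker.track_sequence(
        top, box, tracker.TrackerConfig(bs_enabled=False)
    )
    return {
        "traj": traj,
        "scene": scene,
        "top": top,
        "side": side,
        "truth": truth,
        "rec_bs": rec_bs,
        "ev_bs": ev_bs,
        "rec_kcf": rec_kcf,
    }
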