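import numpy as np
import pytest

from leadtrack import BeamGeometry, LeadTipModel, default_metas


@pytest.fixture(scope="session")
def geom():
    return BeamGeometry()


@pytest.fixture(scope="session")
def lead():
    return LeadTipModel(planning_position=(0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def static_scan(geom, lead):
    """Noiseless 40-frame scan of a static tip offset (3, -2, 5) mm."""
    from leadtrack import render_projection

    tip = np.array([3.0, -2.0, 5.0])
    metas = default_metas(40)
    stack = np.stack(
        [render_projection(tip, lead.axis, m.gantry_angle, geom) for m in metas]
    )
    return {"tip": tip, "metas": metas, "stack": stack}


def pearson_ncc_oracle(region: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Double-loop Pearson correlation of template vs every covered patch."""
    tr, tc = template.shape
    out = np.zeros((region.shape[0] - tr + 1, region.shape[1] - tc + 1))
    tm = template - template.mean()
    tnorm = np.sqrt((tm**2).sum())
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            patch = region[r : r + tr, c : c + tc]
            pm = patch - patch.mean()
            denom = np.sqrt((pm**2).sum()) * tnorm
            out[r, c] = 0.0 if denom == 0 else (pm * tm).sum() / denom
    return out
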