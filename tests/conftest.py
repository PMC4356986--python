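import numpy as np
import pytest

from cellxrf import phantom, pipeline


@pytest.fixture(scope="session")
def default_phantom():
    """One generated default phantom scan, shared across read-only tests."""
    cfg = phantom.PhantomConfig(seed=42)
    truth, stack, saxs = phantom.generate_phantom(cfg)
    return cfg, truth, stack, saxs


@pytest.fixture(scope="session")
def small_study():
    """A reduced exposure design (one control + the high exposures) for
    fast pipeline-level tests."""
    conditions = tuple(c for c in pipeline.DEMO_STUDY
                       if c.label in ("A", "E", "F", "L"))
    return pipeline.StudyConfig(conditions=conditions, n_replicates=2, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
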