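import numpy as np
import pytest

from attnmdp.engine import EngineConfig

#: Tight-convergence settings used wherever a test compares converged
#: posteriors against an exact oracle.
CONVERGED = EngineConfig(n_iterations=128, step_size=1.0, tol=1e-12)


@pytest.fixture(scope="session")
def colour_shape_inf():
    from attnmdp.tasks import build_colour_shape

    return build_colour_shape()


@pytest.fixture(scope="session")
def colour_shape_z0():
    from attnmdp.tasks import build_colour_shape

    return build_colour_shape(z_shape=0.0)


@pytest.fixture(scope="session")
def face_task():
    from attnmdp.tasks import build_face

    return build_face()
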