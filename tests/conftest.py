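"""Shared fixtures: the expensive whole-heart pipeline is built once.

The default-resolution pipeline (heart 2.5 mm, torso 8 mm, seed 7) is a
session fixture; scenario runs derive from it so lead fields, tree
growth, fascicular tuning and the AVN tuning are computed exactly once.
"""

import numpy as np
import pytest

from vheart import Pipeline, Scenario, TissueEP, build_slab
from vheart.activation import EikonalSolver


PIPELINE_SEED = 7


@pytest.fixture(scope="session")
def pipeline():
    pipe = Pipeline(seed=PIPELINE_SEED)
    pipe.tune_avn()
    return pipe


@pytest.fixture(scope="session")
def sinus_run(pipeline):
    return pipeline.run_scenario(Scenario(seed=PIPELINE_SEED))


@pytest.fixture(scope="session")
def lbbb_run(pipeline):
    return pipeline.run_scenario(Scenario(block="left", seed=PIPELINE_SEED))


@pytest.fixture(scope="session")
def rbbb_run(pipeline):
    return pipeline.run_scenario(Scenario(block="right", seed=PIPELINE_SEED))


@pytest.fixture(scope="session")
def heart(pipeline):
    return pipeline.heart


def slab_activation(size, axis, label, edge=2.5, fiber_dir=(1, 0, 0)):
    """Solve a planar wave on a slab stimulated at the axis=0 face."""
    slab = build_slab(size=size, edge_length=edge, fiber_dir=fiber_dir,
                      label=label)
    solver = EikonalSolver(slab, TissueEP())
    src_nodes = np.where(slab.nodes[:, axis] == 0.0)[0]
    amap = solver.solve([(int(i), 0.0) for i in src_nodes])
    return slab, amap
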