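import numpy as np
import pytest

import interactreg as ir
from interactreg.panel import combine_folds


def two_axis_folds(panel, n_blocks=4):
    """Temporal block folds plus a two-group spatial split (robustness axes)."""
    temporal = ir.make_folds(panel, "temporal_blocks", n_blocks=n_blocks)
    counties = sorted({c for c, _ in panel.rows})
    groups = {c: ("A" if i < len(counties) // 2 else "B")
              for i, c in enumerate(counties)}
    spatial = ir.make_folds(panel, "spatial_holdout", groups=groups)
    return combine_folds(temporal, spatial)


@pytest.fixture(scope="session")
def reference_panel():
    """The reference synthetic scenario (n=1000) with its ground truth."""
    panel, truth = ir.generate_panel(ir.reference_config(seed=0))
    return panel, truth


@pytest.fixture(scope="session")
def small_panel():
    """A light panel (n=60) for fast pipeline tests."""
    config = ir.SynthConfig(n_counties=6, year_start=2001, year_end=2010, seed=7)
    panel, truth = ir.generate_panel(config)
    return panel, truth


@pytest.fixture()
def identity_scaler():
    def make(names):
        return ir.Scaler(names=list(names), mins=np.zeros(len(names)),
                         maxs=np.ones(len(names)))
    return make
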