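import numpy as np
import pandas as pd
import pytest

from dstormcount import (KineticsSpec, LocalizationTable, STRAND_PRESETS,
                         calibration_field, simulate_acquisition)


def make_table(frames, xs, ys, photons=None, precision=10.0, **kw):
    n = len(frames)
    df = pd.DataFrame({
        "frame": frames,
        "x": xs,
        "y": ys,
        "photons": photons if photons is not None else np.full(n, 1000.0),
        "precision": np.full(n, precision) if np.isscalar(precision) else precision,
        "id": np.arange(n),
    })
    return LocalizationTable(df, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


#: low-duty-cycle kinetics for desk-scale acquisitions (see docs/methods.md)
DESK_KINETICS = KineticsSpec(mean_off_frames=2000.0,
                             bleach_prob_per_on_frame=0.02)
DESK_N_FRAMES = 4000


@pytest.fixture(scope="session")
def small_calibration():
    """A 120-strand 500 bp calibration acquisition shared across tests."""
    cfg = calibration_field(STRAND_PRESETS["linear500"], n_strands=120,
                            kinetics=DESK_KINETICS, n_frames=DESK_N_FRAMES,
                            seed=424242)
    return simulate_acquisition(cfg)
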