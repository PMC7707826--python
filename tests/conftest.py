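"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from arpsyn import synthetic_data as sd
from arpsyn.trace_analysis import Condition


@pytest.fixture(scope="session")
def small_fit_preset() -> sd.PyrenePreset:
    """Compact noise-free Dip1 titration used by the fitting tests.

    Three Dip1 concentrations plus the actin-alone control, sampled at 20 s
    over 1600 s: enough structure to identify the activation constants while
    keeping global fits fast.
    """
    conds = [Condition(actin_uM=3.0)] + [
        Condition(actin_uM=3.0, arp23_nM=50.0, dip1_uM=d)
        for d in (0.5, 2.5, 10.0)
    ]
    return sd.PyrenePreset("fit-test", conds, noise_sigma_frac=0.0,
                           t_max_s=1600.0, dt_s=20.0)


@pytest.fixture(scope="session")
def small_fit_set(small_fit_preset):
    ts, truth = sd.gen_pyrene(small_fit_preset, 0)
    return ts, truth


@pytest.fixture(scope="session")
def wt_cells():
    return sd.gen_patches("wt", 10, 5)
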