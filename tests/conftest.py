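import numpy as np
import pandas as pd
import pytest

import hemogam as hg


@pytest.fixture(scope="session")
def sin_data():
    """Noisy sine data for univariate smooth tests: y = sin(2*pi*x) + noise."""
    rng = np.random.default_rng(42)
    n = 500
    x = rng.uniform(0.0, 1.0, n)
    y = np.sin(2 * np.pi * x) + rng.normal(0.0, 0.2, n)
    return pd.DataFrame({"x": x}), y


@pytest.fixture(scope="session")
def pp_beats():
    """Default synthetic pulse-pressure series (true PPV = 15%)."""
    return hg.gen_pp_series(hg.PPGeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def cvp_dataset():
    """30 s of synthetic CVP at 125 Hz, with the x'-depth interaction on."""
    cfg = hg.CVPGeneratorConfig(seed=5, interaction_gain=0.5)
    wave, ann, truth = hg.gen_cvp_wave(cfg)
    seg = hg.WaveformSegment.from_frame(wave)
    table = hg.build_cvp_table(seg, ann["qrs_times"], ann["insp_starts"],
                               pr_interval=0.15)
    return table, truth


def smooth_design(x, k=10, basis="natural"):
    """Intercept + one centered smooth of x: the workhorse test design."""
    if basis == "natural":
        b = hg.cubic_basis(hg.make_knots(x, k), natural=True)
    elif basis == "cyclic":
        b = hg.cyclic_cubic_basis(hg.KnotVector(np.linspace(0, 1, k)))
    else:
        b = hg.cubic_basis(hg.make_knots(x, k), natural=False)
    return (
        hg.GAMDesign()
        .add_intercept()
        .add_smooth("s", hg.apply_centering(b, x), "x")
    )
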