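import matplotlib

matplotlib.use("Agg", force=True)

import numpy as np
import pytest

import combokit as ck


@pytest.fixture
def tiny_experiment():
    """Minimal well-formed 2x2 checkerboard (control + one dose each)."""
    return ck.CombinationExperiment.build(
        name="tiny",
        doses_a=[0.0, 1.0],
        doses_b=[0.0, 1.0],
        replicates=[np.array([[100.0, 60.0], [70.0, 50.0]])],
    )


@pytest.fixture
def curves():
    """A representative active Hill-curve pair."""
    return (ck.HillCurve(e_inf=0.0, ec50=1.0, h=1.0),
            ck.HillCurve(e_inf=10.0, ec50=2.0, h=1.5))


@pytest.fixture
def clean_bliss_experiment():
    """Noise-free single-replicate experiment generated under Bliss."""
    spec = ck.SimulationSpec(seed=11, model="bliss", noise_sd=0.0,
                             n_replicates=1, name="clean_bliss")
    return ck.simulate_experiment(spec)


def random_curve(rng, e_inf_range=(0.0, 40.0), h_range=(0.5, 4.0),
                 ec50_decades=(-0.5, 0.5)):
    """Random Hill curve drawn from the screen-realistic parameter box."""
    return ck.HillCurve(
        e_inf=float(rng.uniform(*e_inf_range)),
        ec50=float(10.0 ** rng.uniform(*ec50_decades)),
        h=float(rng.uniform(*h_range)),
    )
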