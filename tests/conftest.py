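import numpy as np
import pytest
from hypothesis import settings

from psapet.kinetics import (ReferenceParameters, frame_average,
                             simulate_reference_tac, simulate_target_tac)
from psapet.synthetic import (DEFAULT_PLASMA_SPEC, RAT_PARAMS,
                              make_plasma_input, make_schedule_fixture,
                              multi_injection_frames,
                              single_injection_schedule, validation_frames)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def row_a():
    return RAT_PARAMS["A"]


@pytest.fixture(scope="session")
def psa_setup(row_a):
    """One noise-free 4.5 nmol partial-saturation scan (rat-A kinetics):
    continuous simulations plus framed total / true-free / reference TACs."""
    plasma = make_plasma_input(DEFAULT_PLASMA_SPEC,
                               single_injection_schedule(4.5))
    frames = validation_frames()
    grid = np.linspace(0.0, 60.0, 601)
    sim = simulate_target_tac(row_a, plasma, grid)
    ref = simulate_reference_tac(
        ReferenceParameters(k1r=row_a.k1, k2r=row_a.k2), plasma, grid)
    return {
        "plasma": plasma,
        "frames": frames,
        "sim": sim,
        "refsim": ref,
        "total": frame_average(sim, frames, "total", roi="hippocampus"),
        "free": frame_average(sim, frames, "free", roi="free"),
        "reference": frame_average(ref, frames, roi="olive nucleus"),
    }


@pytest.fixture(scope="session")
def multiinj_setup(row_a):
    """Noise-free multi-injection scan from rat-A kinetics: the schedule,
    its plasma input, the frame fixture and the framed labelled-ligand TAC."""
    schedule = make_schedule_fixture()
    plasma = make_plasma_input(DEFAULT_PLASMA_SPEC, schedule)
    frames = multi_injection_frames()
    end = frames[0][-1] + frames[1][-1]
    sim = simulate_target_tac(row_a, plasma, np.array([0.0, end]))
    tac = frame_average(sim, frames, "total_hot", roi="hippocampus")
    return {"schedule": schedule, "plasma": plasma, "frames": frames,
            "tac": tac}
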