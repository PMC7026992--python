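import numpy as np
import pytest

from meropk import datasets, pk_core
from meropk.estimation import SubjectData


@pytest.fixture(scope="session")
def median_params():
    return datasets.reference_median_params()


@pytest.fixture(scope="session")
def mean_params():
    return datasets.reference_mean_params()


@pytest.fixture(scope="session")
def ci_1g():
    return datasets.load_regimen("2g_ld_1g_q8h_ci")


@pytest.fixture(scope="session")
def ci_2g():
    return datasets.load_regimen("2g_ld_2g_q8h_ci")


def random_params(rng: np.random.Generator) -> pk_core.StructuralParams:
    """A physiologically plausible random parameter vector for property tests."""
    ref = datasets.load_reference_parameters()
    mean = ref["mean"].to_numpy()
    draw = mean * np.exp(0.4 * rng.standard_normal(len(mean)))
    return pk_core.StructuralParams.from_array(draw)


@pytest.fixture(scope="session")
def rich_subjects(median_params):
    """Noise-free multi-schedule datasets with early kinetic sampling.

    Unlike the trial's flat steady-state window, these sample the loading-dose
    transient and an intermittent-infusion rise/fall, so the data constrain
    the model's identifiable functionals tightly.
    """
    reg_ci = datasets.ci_regimen(1000.0, ld_mg=2000.0, horizon=24.0)
    reg_ei = datasets.ei_regimen(2000.0, infusion_h=4.0, horizon=24.0)
    times = np.array([0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0])
    subjects = []
    for sid, reg in (("a", reg_ci), ("b", reg_ei), ("c", reg_ci), ("d", reg_ei)):
        prof = pk_core.solve_profile(median_params, reg, times)
        subjects.append(
            SubjectData(
                subject_id=sid,
                schedule=reg,
                times=np.concatenate([times, times]),
                analytes=np.array(["plasma"] * len(times) + ["elf"] * len(times), dtype=object),
                values=np.concatenate([prof.c_plasma, prof.c_elf]),
            )
        )
    return subjects
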