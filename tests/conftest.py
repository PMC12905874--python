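import pytest

from hfcea import calibrate_schedule, load_parameter_set, make_arms


def random_valid_values(rng):
    """A random but valid parameter-value set for property checks."""
    return {
        "p_good_adherence_usual": rng.uniform(0.2, 0.8),
        "adherence_gain": rng.uniform(0.0, 0.2),
        "p_exac_good": rng.uniform(0.05, 0.4),
        "p_exac_poor": rng.uniform(0.2, 0.6),
        "p_survive_exac": rng.uniform(0.4, 0.9),
        "p_worsen": rng.uniform(0.05, 0.3),
        "p_survive_no_exac": rng.uniform(0.7, 0.95),
        "u_exacerbation": rng.uniform(0.4, 0.7),
        "u_stable": rng.uniform(0.6, 0.9),
        "u_worsened": rng.uniform(0.4, 0.7),
        "cost_intervention_year1": rng.uniform(100, 1000),
    }


@pytest.fixture(scope="session")
def params():
    return load_parameter_set()


@pytest.fixture(scope="session")
def schedule(params):
    return calibrate_schedule(params)


@pytest.fixture(scope="session")
def arms(params):
    return make_arms(params)  # (intervention, usual_care)
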