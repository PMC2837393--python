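import numpy as np
import pytest

import visuotrack as vt


@pytest.fixture(scope="session")
def constants():
    return vt.TaskConstants()


@pytest.fixture(scope="session")
def young_mean_params():
    """Young-group mean parameters (log10 means of the cohort model)."""
    return vt.SubjectParameters(
        latency_tau=10 ** -0.5879,
        noise_intensity=10 ** -2.7556,
        noise_bandwidth=10 ** 0.9495,
        rho=10 ** -0.7257,
    )


@pytest.fixture(scope="session")
def elderly_mean_params():
    return vt.SubjectParameters(
        latency_tau=10 ** -0.6252,
        noise_intensity=10 ** -2.6408,
        noise_bandwidth=10 ** 0.9039,
        rho=10 ** -0.3010,
    )


@pytest.fixture(scope="session")
def young_controller(constants, young_mean_params):
    plant = vt.assemble_plant(constants, young_mean_params)
    return plant, vt.design_lqg(plant)


@pytest.fixture(scope="session")
def perturbations(constants):
    """Eight shared 60-s perturbation sequences."""
    return vt.generate_perturbations(constants, 8, seed=101)


@pytest.fixture(scope="session")
def young_trials(constants, young_mean_params, perturbations):
    """A young-typical subject's session over the shared perturbations."""
    return vt.simulate_subject(
        constants, young_mean_params, perturbations, seed=202, subject_id="Y0"
    )


@pytest.fixture(scope="session")
def cohort_analyses(constants):
    """Full synthetic experiment: 12 young + 12 elderly subjects, ten 60-s
    trials each (trials 3-10 analyzed), cross-correlation latencies and
    per-trial model fits.  Shared across the acceptance tests."""
    specs = [
        vt.CohortSpec(group="young", n_subjects=12, seed=7),
        vt.CohortSpec(group="elderly", n_subjects=12, seed=7 + 17),
    ]
    subjects = vt.generate_cohort_dataset(
        constants, specs, n_trials=10, pert_seed=7 + 911
    )
    fit_config = vt.FitConfig(n_restarts=1, maxfev=350)
    analyses = vt.analyze_cohort(subjects, constants, fit_config)
    return subjects, analyses


def rand_stable_system(rng, n, m=1, p=1, margin=0.3):
    """Random asymptotically stable system (shifted random A)."""
    A = rng.standard_normal((n, n))
    A = A - (np.max(np.linalg.eigvals(A).real) + margin) * np.eye(n)
    return vt.StateSpaceModel(
        A, rng.standard_normal((n, m)), rng.standard_normal((p, n)),
        np.zeros((p, m)),
    )
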