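import numpy as np
import pytest

from speechconn import (
    Cohort,
    ConnectivityMatrix,
    EffectSpec,
    NoiseSpec,
    Parcellation,
    Subject,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def parcellation():
    return Parcellation.default()


@pytest.fixture(scope="session")
def small_parcellation():
    """10 speech nodes per hemisphere for fast tests."""
    labels = tuple(f"roi{i}" for i in range(10))
    return Parcellation.default(labels)


@pytest.fixture(scope="session")
def null_cohort(parcellation):
    """20 vs 17 subjects, no planted effect, default noise."""
    return simulate_cohort(parcellation, n_case=20, n_control=17, seed=11)


@pytest.fixture(scope="session")
def planted_cohort(parcellation):
    """8-edge connected component weakened to 0.4x in the case group."""
    return simulate_cohort(
        parcellation,
        n_case=20,
        n_control=17,
        effect=EffectSpec(target_edges=8, effect_multiplier=0.4),
        noise=NoiseSpec(sigma=0.15),
        seed=12,
    )


def cohort_from_arrays(case_stack, control_stack, layout="intra_left", severities=None):
    """Build a cohort directly from per-subject weight arrays."""
    labels = tuple(f"n{i}" for i in range(case_stack.shape[1]))
    subjects, mats = [], []
    k = 0
    for stack, group in ((case_stack, "case"), (control_stack, "control")):
        for i, w in enumerate(stack):
            sev = None
            if group == "case" and severities is not None:
                sev = float(severities[i])
            subjects.append(Subject(id=f"s{k:03d}", group=group, severity=sev))
            mats.append(
                ConnectivityMatrix(w, labels, layout, symmetric=layout != "commissural")
            )
            k += 1
    return Cohort(subjects=subjects, matrices={layout: mats})


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)
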