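import numpy as np
import pytest

from hemotrace import synth


@pytest.fixture(scope="session")
def clean_record():
    """30 s artifact-free record at 120/80, 75 bpm."""
    spec = synth.SignalSpec(duration=30.0, heart_rate=75, sbp=120, dbp=80)
    return synth.synth_signal(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_record():
    """60 s record with a 30% artifact burden."""
    spec = synth.SignalSpec(duration=60.0, heart_rate=75, artifact_fraction=0.3)
    return synth.synth_signal(spec, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Signal-level cohort small enough for fast end-to-end tests."""
    cspec = synth.CohortSpec(
        n_subjects=60,
        prevalence=0.15,
        seed=5,
        signal_spec=synth.SignalSpec(duration=20.0, artifact_fraction=0.1),
    )
    return synth.synth_cohort(cspec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Extracted feature table for the small cohort."""
    from hemotrace.pipeline import extract_cohort_features

    table, excluded = extract_cohort_features(small_cohort)
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def exact_mw_p(x, y):
    """Full-enumeration two-tailed Mann–Whitney oracle (assumes no ties)."""
    import itertools

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(combo)]
        us.append(r.sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    mean_u = len(x) * len(y) / 2
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)


@pytest.fixture(scope="session")
def mw_enumeration_oracle():
    return exact_mw_p
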