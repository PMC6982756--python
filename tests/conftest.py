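import numpy as np
import pytest

from wearload import (
    FeatureSetSpec,
    default_activity_models,
    featurize_session,
    generate_session,
)
from wearload.sensor_io import sessions_to_records
from wearload.features import featurize_records


@pytest.fixture(scope="session")
def models():
    return default_activity_models()


@pytest.fixture(scope="session")
def session240():
    """One default 8 x 30 s routine session (240 records)."""
    return generate_session(seed=42)


@pytest.fixture(scope="session")
def pruned_vectors(session240):
    return featurize_session(session240, FeatureSetSpec.pruned())


def make_corpus_vectors(seed: int, n_sessions: int = 3, spec: FeatureSetSpec | None = None):
    """Labeled feature matrix from several seeded routine sessions."""
    if spec is None:
        spec = FeatureSetSpec.pruned()
    base = np.random.SeedSequence(seed).generate_state(n_sessions) % (2**31)
    sessions = [generate_session(seed=int(s)) for s in base]
    return featurize_records(sessions_to_records(sessions), spec)
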