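import numpy as np
import pytest

import amylometa as am


@pytest.fixture(scope="session")
def suite():
    """Deterministic synthetic scorer suite shared across tests."""
    return am.synthetic_scorer_suite(seed=7)


@pytest.fixture(scope="session")
def hexset(suite):
    """A 116+/162- labelled hexapeptide dataset from the default generator."""
    return am.gen_labelled_hexapeptides(am.SyntheticConfig(seed=7), scorers=suite)


@pytest.fixture(scope="session")
def trained(suite, hexset):
    """End-to-end trained artefacts: (model, features, labels, threshold).

    Stepwise-selected logistic meta-model on the session hexapeptide set,
    with an upper-left threshold estimated from leave-one-out scores.
    """
    X = am.features_for_peptides(hexset.peptides, suite)
    y = np.asarray(hexset.labels)
    selected, _ = am.stepwise_select(X, y)
    model = am.fit_logistic(X[selected], y)
    cv = am.cross_validated_scores(X[selected], y, am.CVScheme("loo"))
    threshold = am.select_threshold(cv, y, criterion="upper-left")
    return model, X[selected], y, threshold


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
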