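import numpy as np
import pytest

from emgctl import Gesture, default_profiles, gen_training_set, train_model
from emgctl.svm import SvmModel


@pytest.fixture(scope="session")
def clean_profiles():
    """Noiseless activation profiles (separable limit)."""
    return default_profiles(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_profiles():
    return default_profiles(noise_sd=0.08)


@pytest.fixture(scope="session")
def complete_model(noisy_profiles):
    """A 4-class model trained on the default noisy generator."""
    X, y = gen_training_set(noisy_profiles, 3, mode="COMPLETE", seed=11)
    return train_model(X, y)


@pytest.fixture(scope="session")
def reduced_model(noisy_profiles):
    X, y = gen_training_set(noisy_profiles, 3, mode="REDUCED", seed=11)
    return train_model(X, y, mode="REDUCED")


def random_model(rng, n_classes=None, max_sv_per_class=10, n_features=4):
    """Construct a random small packed model directly (no training)."""
    ncl = n_classes or int(rng.integers(2, 5))
    counts = rng.integers(1, max_sv_per_class + 1, size=ncl)
    ns = int(counts.sum())
    return SvmModel(
        n_features=n_features,
        n_classes=ncl,
        gamma=float(rng.uniform(0.05, 2.0)),
        class_labels=list(range(ncl)),
        sv_counts=counts,
        support_vectors=rng.normal(0, 1.5, size=(ns, n_features)),
        coefficients=rng.normal(0, 1.0, size=(ns, ncl - 1)),
        rho=rng.normal(0, 0.5, size=ncl * (ncl - 1) // 2),
    )


@pytest.fixture
def two_class_toy():
    """One SV per class, s1=(1,0), s2=(0,1), C=+1/-1, rho=0, gamma=1."""
    return SvmModel(
        n_features=2, n_classes=2, gamma=1.0,
        class_labels=[Gesture.OPEN_HAND, Gesture.POWER_GRASP],
        sv_counts=np.array([1, 1]),
        support_vectors=np.array([[1.0, 0.0], [0.0, 1.0]]),
        coefficients=np.array([[1.0], [-1.0]]),
        rho=np.array([0.0]),
    )
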