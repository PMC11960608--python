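import numpy as np
import pytest

from relpatlak import (InputFunction, PhantomConfig, build_phantom,
                       late_schedule)


@pytest.fixture(scope="session")
def feng():
    return InputFunction.feng()


@pytest.fixture(scope="session")
def late_sched():
    return late_schedule()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced phantom grid for unit tests."""
    return build_phantom(PhantomConfig(shape=(20, 20, 40)))


@pytest.fixture(scope="session")
def small_noise_free(small_spec, feng, late_sched):
    from relpatlak.phantom import noise_free_dynamic
    return noise_free_dynamic(small_spec, feng, late_sched)
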