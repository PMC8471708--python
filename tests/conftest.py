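import warnings

import pytest

from helichir import load_fixture

COIL_FIXTURES = ("lff_pm3", "lff_amber", "dff_pm3", "dff_amber")


@pytest.fixture(scope="session")
def published_coils():
    """The four published one-coil dipole sets, keyed by fixture name.

    Loading dff_pm3 emits advisory-magnitude warnings by design; they are
    suppressed here and tested explicitly in the tables tests.
    """
    coils = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in COIL_FIXTURES:
            coils[name] = load_fixture(name)
    return coils
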