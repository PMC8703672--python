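import pytest

import its2barcode as ib


@pytest.fixture(scope="session")
def default_dataset():
    """The default two-species synthetic design, seed 1."""
    return ib.generate_dataset(ib.default_spec(1))


@pytest.fixture(scope="session")
def reference_and_template():
    return ib.make_reference(ib.default_spec(1))
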