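import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_data():
    """The packaged synthetic 22x12 example trial."""
    from crtbayes import make_example_dataset
    return make_example_dataset()
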