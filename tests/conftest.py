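import pytest

from pathograph import fixtures as fx


@pytest.fixture
def her2_doc():
    return fx.exemplar("her2_fig4")


@pytest.fixture
def follicle_doc():
    return fx.exemplar("follicle_fig5")


@pytest.fixture
def cervical_doc():
    return fx.exemplar("cervical_fig6")


@pytest.fixture
def lymphoma_doc():
    return fx.exemplar("lymphoma_fig7")


@pytest.fixture
def cervical_slide_doc():
    return fx.exemplar("cervical_slide_fig11")


@pytest.fixture
def lymphoma_slide_doc():
    return fx.exemplar("lymphoma_slide_fig7")
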