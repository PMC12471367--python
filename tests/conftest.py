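import logging

import pytest

from amphiscan import make_fixture_table1


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # validation warnings are part of the contract; keep test output clean
    logging.getLogger("amphiscan").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def fixture_set():
    """The packaged eight-variant spectra plus the known-AM table."""
    return make_fixture_table1(seed=0)


@pytest.fixture(scope="session")
def arc_spectra(fixture_set):
    spectra, _ = fixture_set
    return {s.spectrum_id: s for s in spectra}
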