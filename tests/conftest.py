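"""Shared fixtures: the packaged China dataset, prepared datasets per
pollutant, and converged model fits (session-scoped — the NLS fits take a
couple of thousand sweeps each and every test that inspects them can share
one solve)."""

import pytest

import greycast as gc

POLLUTANTS = ("WDPC", "SO2", "Dust")

#: Solver settings used for reproduction runs: fully converged optimum.
REPRO_NLS = dict(tol=1e-8, max_iter=5000)


@pytest.fixture(scope="session")
def fixture_table():
    return gc.load_fixture()


@pytest.fixture(scope="session")
def prepared(fixture_table):
    return {
        name: gc.prepare(fixture_table[name], fixture_table["GDP"])
        for name in POLLUTANTS
    }


@pytest.fixture(scope="session")
def gm_fits(prepared):
    return {name: gc.fit_gm1n(data) for name, data in prepared.items()}


@pytest.fixture(scope="session")
def nls_fits(prepared):
    cfg = gc.NLSConfig(**REPRO_NLS)
    return {name: gc.fit_nls(data, cfg) for name, data in prepared.items()}


@pytest.fixture(scope="session")
def nls_lm_fits(prepared):
    cfg = gc.NLSConfig(**REPRO_NLS)
    return {name: gc.fit_nls_lm(data, cfg) for name, data in prepared.items()}
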