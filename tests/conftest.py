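import pytest
import sympy as sp

from dnalie.algebra_tools import LieAlgebra
from dnalie.cli_io import generate_fixtures
from dnalie.lie_engine import determining_system, solve_determining


@pytest.fixture(scope="session")
def algebra():
    return LieAlgebra.standard()


@pytest.fixture(scope="session")
def solved_basis():
    return solve_determining(determining_system(ansatz_degree=2))


@pytest.fixture(scope="session")
def fixture_set():
    return generate_fixtures(seed=0)


@pytest.fixture(scope="session")
def catalogue_entries():
    from dnalie.aux_method import verify_catalogue
    import numpy as np

    return verify_catalogue(np.random.default_rng(0))


@pytest.fixture(scope="session")
def consistent_waves(catalogue_entries):
    from dnalie.aux_method import build_solutions

    return build_solutions(entries=catalogue_entries, mode="consistent")


@pytest.fixture(scope="session")
def step_reports(algebra):
    from dnalie.algebra_tools import validate_printed_steps

    return validate_printed_steps(algebra)
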