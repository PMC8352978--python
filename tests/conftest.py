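import pytest

from emekit import BuildConfig, ToySpec, build_me_problem, generate_toy_model, solve


@pytest.fixture(scope="session")
def toy_doc():
    """Default toy model document (seed 1, overflow topology)."""
    return generate_toy_model(ToySpec())


@pytest.fixture(scope="session")
def me_build(toy_doc):
    """EFL.cb build of the toy model at desk-scale discretization (N=8)."""
    return build_me_problem(
        toy_doc.model, toy_doc.network, BuildConfig(n_bins=8)
    )


@pytest.fixture(scope="session")
def me_solution(me_build):
    sol = solve(me_build.problem)
    assert sol.status == "optimal"
    return sol
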