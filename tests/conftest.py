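import pytest

from mtow import (
    ToySpec,
    make_toy_model,
    make_synthetic_ccm_data,
    solve_feasible_flux,
    split_reversible,
)


@pytest.fixture(scope="session")
def linear_toy():
    """3-metabolite linear pathway, both internal steps strongly favourable."""
    spec = ToySpec(n_steps=3, dg0s=[-10.0, -10.0])
    model, medium = make_toy_model(spec)
    return model, medium


@pytest.fixture(scope="session")
def linear_toy_split(linear_toy):
    model, medium = linear_toy
    split = split_reversible(model)
    flux = solve_feasible_flux(split, medium)
    return split, medium, flux


@pytest.fixture(scope="session")
def tradeoff_toy():
    """4-step chain with pinned boundary concentrations.

    The total chemical-potential drop available (15 kJ/mol from the
    standard energies plus the fixed boundary log-ratio) is below what
    saturating all three reactions at the driving-force ceiling α would
    need, so metabolite load and enzyme cost genuinely trade off.
    """
    spec = ToySpec(n_steps=4, dg0s=[-5.0, -5.0, -5.0], boundary_concs=(1.0, 0.01))
    model, medium = make_toy_model(spec)
    split = split_reversible(model)
    flux = solve_feasible_flux(split, medium)
    return split, medium, flux


@pytest.fixture(scope="session")
def ccm_noise_free():
    """Noise-free synthetic component-contribution training data."""
    return make_synthetic_ccm_data(
        n_compounds=30, n_groups=8, n_train_reactions=20, noise_sd=0.0, seed=42
    )
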