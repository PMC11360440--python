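import pytest

from polyel_eos import validate_mixture


@pytest.fixture
def pa_pc_s():
    """Asymmetric PA(50)/PC(1)/solvent mixture used throughout."""
    return validate_mixture(N_A=50, N_C=1, phi_A=0.05, phi_S=0.9)


@pytest.fixture
def monomeric():
    """Fully charged monomeric electrolyte (N_A = N_C = 1)."""
    return validate_mixture(N_A=1, N_C=1, phi_A=0.25, phi_S=0.5)


@pytest.fixture
def coacervate_template():
    """Template for the coacervation system: PA(50)/PC(1) in solvent."""
    return validate_mixture(N_A=50, N_C=1, phi_A=0.01, phi_S=0.98)
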