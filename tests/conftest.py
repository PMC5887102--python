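import numpy as np
import pytest

import triadet as td


@pytest.fixture
def wt_rates() -> td.RateSet:
    """Wild-type hole-transfer rates of the three-state chain (ns^-1)."""
    return td.RateSet(870.0, 193.0, 199.0, 25.0)


@pytest.fixture
def triad_hamiltonian() -> td.CTHamiltonian:
    """Small triad Hamiltonian with Trp-like energies and meV couplings."""
    sites = [
        td.ChargeSite("A", -5.8, residue_name="TRP", role="donor"),
        td.ChargeSite("B", -5.8, residue_name="TRP"),
        td.ChargeSite("C", -5.9, residue_name="TRP", role="acceptor"),
    ]
    return td.assemble_hamiltonian(
        sites, {("A", "B"): 0.008, ("B", "C"): 0.0042}
    )


@pytest.fixture
def downhill_hamiltonian() -> td.CTHamiltonian:
    """Strongly downhill 3-site hole Hamiltonian (0.4 eV steps)."""
    sites = [
        td.ChargeSite("A", 0.0, role="donor"),
        td.ChargeSite("B", -0.4),
        td.ChargeSite("C", -0.8, role="acceptor"),
    ]
    return td.assemble_hamiltonian(
        sites, {("A", "B"): 0.016, ("B", "C"): 0.008}
    )
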