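"""Physical constants and unit conversions.

Energies are stored in eV throughout the package; electronic couplings are
reported in meV only at interface boundaries.  Times mix fs (propagation
steps), ps (trajectories) and ns (rate constants); conversions are explicit.
"""

#: Reduced Planck constant in eV·ps.
HBAR_EV_PS: float = 6.582119569e-4

#: Boltzmann constant in eV/K.
KB_EV_PER_K: float = 8.617333e-5

#: Conversion factors.
EV_PER_MEV: float = 1e-3
MEV_PER_EV: float = 1e3
PS_PER_FS: float = 1e-3
PS_PER_NS: float = 1e3
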