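"""Bridge-mediated (super-exchange) tunnelling couplings.

When a large energy barrier separates donor and acceptor, charge transfer
proceeds by virtual tunnelling through the bridge states.  The Hamiltonian
is partitioned into a donor/acceptor block and a bridge block; the bridge is
folded into an effective 2×2 Hamiltonian

    H_eff[D, A] = β_DA + Σ_ij β_Di G_ij(ε_tun) β_jA,

where G(ε) = (εI − H_bridge)^(−1) is the bridge Green's function and the
tunnelling energy ε_tun is the average of the eigenvalues of H_eff itself —
a fixed point solved here by iteration.  The off-diagonal of the converged
H_eff is the tunnelling coupling T_DA.

The empirical pathways product model (per-step decay factors for covalent,
hydrogen-bond and through-space steps) is provided as a cheap geometric
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from .constants import MEV_PER_EV
from .errors import ConvergenceError, InputError, PoleError
from .hamiltonian import CTHamiltonian

__all__ = [
    "Partition",
    "EffectiveCoupling",
    "PathwayStep",
    "PathwayParams",
    "greens_function",
    "effective_hamiltonian",
    "tunnelling_coupling",
    "pathway_coupling",
]


@dataclass(frozen=True)
class Partition:
    """Donor/acceptor/bridge split of a CT Hamiltonian's sites."""

    donor_id: str
    acceptor_id: str
    bridge_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "bridge_ids", tuple(self.bridge_ids))
        if self.donor_id == self.acceptor_id:
            raise InputError("donor and acceptor must differ")
        if self.donor_id in self.bridge_ids or self.acceptor_id in self.bridge_ids:
            raise InputError("bridge ids must be disjoint from donor/acceptor")
        if len(set(self.bridge_ids)) != len(self.bridge_ids):
            raise InputError("duplicate bridge ids")


@dataclass(frozen=True)
class EffectiveCoupling:
    """Converged effective 2×2 Hamiltonian and derived quantities."""

    t_da_mev: float
    epsilon_tun: float
    greens: np.ndarray          # bridge-space Green's function, eV^-1
    effective_h: np.ndarray     # 2×2, eV; [0,1] is T_DA
    iterations: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_da_mev):
            raise InputError("T_DA is not finite")
        if not np.allclose(self.effective_h, self.effective_h.T, atol=1e-12):
            raise InputError("effective Hamiltonian must be symmetric")


def greens_function(
    bridge_block: np.ndarray, epsilon: float, pole_margin: float = 1e-6
) -> np.ndarray:
    """Bridge Green's function G(ε) = (εI − H_bridge)^(−1), in eV^-1.

    Raises :class:`PoleError` when ε lies within ``pole_margin`` of a bridge
    eigenvalue, naming the offending eigenvalue.
    """
    hb = np.atleast_2d(np.asarray(bridge_block, dtype=float))
    if hb.shape[0] != hb.shape[1]:
        raise InputError(f"bridge block must be square, got {hb.shape}")
    eigs = np.linalg.eigvalsh(hb)
    gaps = np.abs(epsilon - eigs)
    k = int(np.argmin(gaps))
    if gaps[k] < pole_margin:
        raise PoleError(
            f"tunnelling energy {epsilon:.9g} eV is within {pole_margin:g} eV of "
            f"bridge eigenvalue {eigs[k]:.9g} eV",
            eigenvalue=float(eigs[k]),
        )
    return np.linalg.inv(epsilon * np.eye(hb.shape[0]) - hb)


def _build_effective(
    eps_d: float, eps_a: float, beta_da: float,
    beta_d: np.ndarray, beta_a: np.ndarray,
    hb: np.ndarray, epsilon: float, pole_margin: float,
) -> tuple[np.ndarray, np.ndarray]:
    g = greens_function(hb, epsilon, pole_margin)
    h_eff = np.array(
        [
            [eps_d + beta_d @ g @ beta_d, beta_da + beta_d @ g @ beta_a],
            [beta_da + beta_a @ g @ beta_d, eps_a + beta_a @ g @ beta_a],
        ]
    )
    return h_eff, g


def effective_hamiltonian(
    H: CTHamiltonian,
    part: Partition,
    self_consistent: bool = True,
    tol: float = 1e-9,
    max_iter: int = 100,
    pole_margin: float = 1e-6,
) -> EffectiveCoupling:
    """Fold the bridge into a 2×2 donor/acceptor Hamiltonian.

    The tunnelling energy starts at the mean of the donor/acceptor diagonal
    energies and, when ``self_consistent``, is iterated to the mean of the
    eigenvalues of H_eff (equivalently half its trace) until it moves by
    less than ``tol`` eV.  Diagonals of H_eff are dressed with the analogous
    self-energy terms β_Di G_ij β_jD so the eigenvalue-average definition is
    self-consistent.
    """
    d = H.index(part.donor_id)
    a = H.index(part.acceptor_id)
    bridge = [H.index(b) for b in part.bridge_ids]
    m = H.matrix
    eps_d, eps_a, beta_da = m[d, d], m[a, a], m[d, a]

    if not bridge:
        h_eff = np.array([[eps_d, beta_da], [beta_da, eps_a]])
        return EffectiveCoupling(
            t_da_mev=float(beta_da * MEV_PER_EV),
            epsilon_tun=float((eps_d + eps_a) / 2.0),
            greens=np.zeros((0, 0)),
            effective_h=h_eff,
            iterations=0,
        )

    hb = m[np.ix_(bridge, bridge)]
    beta_d = m[d, bridge]
    beta_a = m[bridge, a]

    epsilon = (eps_d + eps_a) / 2.0
    trace = [epsilon]
    h_eff, g = _build_effective(eps_d, eps_a, beta_da, beta_d, beta_a,
                                hb, epsilon, pole_margin)
    iterations = 1
    if self_consistent:
        for iterations in range(1, max_iter + 1):
            new_eps = float(np.trace(h_eff) / 2.0)
            trace.append(new_eps)
            if abs(new_eps - epsilon) < tol:
                epsilon = new_eps
                break
            epsilon = new_eps
            h_eff, g = _build_effective(eps_d, eps_a, beta_da, beta_d, beta_a,
                                        hb, epsilon, pole_margin)
        else:
            raise ConvergenceError(
                f"tunnelling energy did not converge in {max_iter} iterations",
                trace=trace,
            )

    # symmetrize away last-bit asymmetry from the two quadratic forms
    h_eff = (h_eff + h_eff.T) / 2.0
    return EffectiveCoupling(
        t_da_mev=float(h_eff[0, 1] * MEV_PER_EV),
        epsilon_tun=float(epsilon),
        greens=g,
        effective_h=h_eff,
        iterations=iterations,
    )


def tunnelling_coupling(H: CTHamiltonian, part: Partition, **kwargs) -> float:
    """Super-exchange tunnelling coupling T_DA in meV."""
    return effective_hamiltonian(H, part, **kwargs).t_da_mev


# ---------------------------------------------------------------------------
# Pathways product model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayParams:
    """Per-step decay constants of the empirical pathways model.

    covalent step: ε_C; hydrogen bond: ε_C² exp(−β(R − R_HB));
    through-space: ε_C exp(−β(R − R_TS)); distances R in Å.
    """

    covalent: float = 0.6
    hbond_prefactor: float = 0.36
    beta: float = 1.7          # Å^-1
    hbond_offset: float = 2.8  # Å
    space_offset: float = 1.4  # Å


@dataclass(frozen=True)
class PathwayStep:
    """One step of a tunnelling pathway."""

    kind: str                  # covalent | hydrogen_bond | through_space
    length: float = 0.0        # Å, unused for covalent steps

    def __post_init__(self) -> None:
        if self.kind not in ("covalent", "hydrogen_bond", "through_space"):
            raise InputError(f"unknown step kind {self.kind!r}")
        if self.kind != "covalent" and self.length < 0:
            raise InputError(f"step length must be >= 0, got {self.length}")


def pathway_coupling(
    steps: list[PathwayStep], params: PathwayParams = PathwayParams()
) -> float:
    """Relative (dimensionless) coupling: product of per-step decay factors."""
    if not steps:
        raise InputError("pathway must contain at least one step")
    total = 1.0
    for step in steps:
        if step.kind == "covalent":
            total *= params.covalent
        elif step.kind == "hydrogen_bond":
            total *= params.hbond_prefactor * exp(
                -params.beta * (step.length - params.hbond_offset)
            )
        else:
            total *= params.covalent * exp(
                -params.beta * (step.length - params.space_offset)
            )
    return total
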