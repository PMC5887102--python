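"""Stochastic surrogate for non-adiabatic hole propagation along the triad.

A hole wavefunction is propagated over a small fluctuating Hamiltonian with
the exact (eigendecomposition) exponential propagator at every step.  The
explicit protein/solvent environment is replaced by three ingredients that
preserve its mechanistic role:

* Ornstein–Uhlenbeck site-energy noise — thermal fluctuations that
  transiently bring sites into resonance and enable hopping;
* a charge-response term — an auxiliary polarization coordinate per site
  relaxes toward the current occupation and lowers that site's energy by up
  to λ_i/polarization_scale, the outer-sphere reorganization stabilization
  that traps the hole after each hop;
* decoherence — nuclear-induced loss of electronic coherence, applied in
  trajectories as stochastic charge localization (a quantum-jump unravelling
  of coherence damping at rate 1/τ_d: the wavefunction collapses onto one
  site drawn from the instantaneous occupations).  Mean-field propagation
  with deterministic coherence damping alone equilibrates every population
  to 1/n (its hopping flux is proportional to the occupation difference, an
  infinite-temperature artifact of classical noise); localized trajectories
  instead engage the reorganization asymmetry, so back-transfer out of a
  relaxed site is strongly suppressed and the hole ratchets downhill.

The matrix is interpreted as the Hamiltonian of the transferred hole:
lower diagonal entries are more stable for the hole.  Only oxidisable sites
belong in the propagated subspace (the flavin is the counter-ion, not a
hopping site).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .constants import HBAR_EV_PS, PS_PER_FS
from .errors import InputError
from .hamiltonian import CTHamiltonian
from .kinetics import OccupationEnsemble

__all__ = [
    "FluctuationModel",
    "PropagationConfig",
    "WaveState",
    "OccupationTrajectory",
    "sample_ou",
    "step_wavefunction",
    "apply_charge_response",
    "apply_decoherence",
    "run_trajectory",
    "ensemble_average",
]


@dataclass(frozen=True)
class FluctuationModel:
    """Ornstein–Uhlenbeck parameters of the fluctuating Hamiltonian.

    ``site_sd`` (eV) and ``site_corr_time_ps`` give the stationary spread
    and correlation time of each diagonal entry; optional coupling noise
    applies one independent OU process to every nonzero off-diagonal.
    """

    site_sd: tuple[float, ...]
    site_corr_time_ps: tuple[float, ...]
    coupling_sd: float = 0.0
    coupling_corr_time_ps: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_sd", tuple(float(s) for s in self.site_sd))
        ct = self.site_corr_time_ps
        if np.isscalar(ct):
            ct = (float(ct),) * len(self.site_sd)
        object.__setattr__(self, "site_corr_time_ps", tuple(float(c) for c in ct))
        if len(self.site_corr_time_ps) != len(self.site_sd):
            raise InputError("site_sd and site_corr_time_ps length mismatch")
        if any(s < 0 for s in self.site_sd) or self.coupling_sd < 0:
            raise InputError("noise sd must be >= 0")
        if any(c <= 0 for c in self.site_corr_time_ps) or self.coupling_corr_time_ps <= 0:
            raise InputError("correlation times must be > 0")


@dataclass(frozen=True)
class PropagationConfig:
    """Numerical and environment-response parameters of a propagation run.

    ``lambda_reorg`` is the per-site outer-sphere reorganization energy in
    eV; the realized stabilization depth is λ_i / ``polarization_scale``.
    ``polarization_scale`` also divides the site-energy noise amplitude,
    mirroring electronic-polarization screening of all environment-induced
    terms.
    """

    total_time_ps: float
    dt_fs: float = 1.0
    lambda_reorg: tuple[float, ...] = (0.7, 0.7, 0.7)
    solvent_relax_time_ps: float = 1.0
    decoherence_time_fs: float | None = 10.0
    polarization_scale: float = 1.4
    seed: int | None = None
    output_dt_ps: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_reorg",
                           tuple(float(x) for x in self.lambda_reorg))
        if not self.dt_fs > 0:
            raise InputError("dt must be > 0")
        if not self.total_time_ps > 0:
            raise InputError("total_time must be > 0")
        if not self.solvent_relax_time_ps > 0:
            raise InputError("solvent_relax_time must be > 0")
        if self.decoherence_time_fs is not None and not self.decoherence_time_fs > 0:
            raise InputError("decoherence_time must be > 0 (or None to disable)")
        if self.polarization_scale < 1:
            raise InputError("polarization_scale must be >= 1")
        if not self.output_dt_ps > 0:
            raise InputError("output_dt must be > 0")


@dataclass(frozen=True)
class WaveState:
    """Complex site amplitudes of the hole wavefunction, normalized to 1."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex)
        object.__setattr__(self, "amplitudes", amp)
        norm = float(np.sum(np.abs(amp) ** 2))
        if abs(norm - 1.0) > 1e-8:
            raise InputError(f"wavefunction norm {norm} deviates from 1 by > 1e-8")

    def occupations(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


@dataclass
class OccupationTrajectory:
    """Per-site hole occupations on a uniform time grid (ps)."""

    time_ps: np.ndarray
    occupations: np.ndarray           # (n_times, n_sites), rows sum to 1
    site_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        if self.occupations.shape != (self.time_ps.size, len(self.site_ids)):
            raise InputError("occupations shape does not match grid / sites")
        if np.any(self.occupations < -1e-9) or np.any(self.occupations > 1 + 1e-9):
            raise InputError("occupations must lie within [0, 1]")
        if np.max(np.abs(self.occupations.sum(axis=1) - 1.0)) > 1e-6:
            raise InputError("occupation rows must sum to 1 within 1e-6")

    @property
    def dt_ps(self) -> float:
        return float(self.time_ps[1] - self.time_ps[0])

    def to_csv(self, path) -> None:
        data = {"time_ps": self.time_ps}
        for k, sid in enumerate(self.site_ids):
            data[f"occ_{sid}"] = self.occupations[:, k]
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccupationTrajectory":
        df = pd.read_csv(path)
        site_ids = tuple(c[len("occ_"):] for c in df.columns if c.startswith("occ_"))
        return cls(
            time_ps=df["time_ps"].to_numpy(),
            occupations=df[[f"occ_{s}" for s in site_ids]].to_numpy(),
            site_ids=site_ids,
        )


def sample_ou(
    sd: float,
    corr_time_ps: float,
    dt_fs: float,
    n_steps: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck series of length ``n_steps``.

    Exact discretization: x' = x·e^(−dt/τ) + sd·sqrt(1 − e^(−2dt/τ))·N(0,1),
    started from the stationary distribution N(0, sd²).
    """
    if sd < 0 or corr_time_ps <= 0 or dt_fs <= 0 or n_steps <= 0:
        raise InputError("sample_ou parameters must be positive (sd >= 0)")
    if sd == 0:
        return np.zeros(n_steps)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rho = np.exp(-dt_fs * PS_PER_FS / corr_time_ps)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    noise = rng.standard_normal(n_steps) * innov_sd
    x0 = rng.standard_normal() * sd
    # x_k = rho x_{k-1} + w_k  via an IIR filter with stationary start
    zi = scipy.signal.lfiltic([1.0], [1.0, -rho], [x0])
    series, _ = scipy.signal.lfilter([1.0], [1.0, -rho], noise, zi=zi)
    return series


def _propagator(h: np.ndarray, dt_fs: float) -> np.ndarray:
    w, v = np.linalg.eigh(h)
    phase = np.exp(-1j * w * (dt_fs * PS_PER_FS) / HBAR_EV_PS)
    return (v * phase) @ v.conj().T


def step_wavefunction(
    h_t: np.ndarray, psi: WaveState | np.ndarray, dt_fs: float
) -> WaveState | np.ndarray:
    """One exact unitary step ψ' = exp(−i H dt/ħ) ψ (H in eV, dt in fs)."""
    h = np.asarray(h_t, dtype=float)
    if not np.allclose(h, h.T, atol=1e-10):
        raise InputError("Hamiltonian must be symmetric")
    u = _propagator(h, dt_fs)
    if isinstance(psi, WaveState):
        return WaveState(u @ psi.amplitudes)
    return u @ np.asarray(psi, dtype=complex)


def apply_charge_response(
    base_energies: np.ndarray,
    occupations: np.ndarray,
    polarization: np.ndarray,
    config: PropagationConfig,
    dt_fs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relax the polarization coordinate toward the occupations and lower
    the site energies accordingly.

    q̄ relaxes toward the occupation vector with time constant
    ``solvent_relax_time_ps``; each diagonal energy is lowered by
    (λ_i / polarization_scale)·q̄_i.  Returns (energies, new q̄).
    """
    dt = config.dt_fs if dt_fs is None else dt_fs
    occ = np.asarray(occupations, dtype=float)
    qbar = np.asarray(polarization, dtype=float)
    alpha = 1.0 - np.exp(-dt * PS_PER_FS / config.solvent_relax_time_ps)
    new_qbar = qbar + alpha * (occ - qbar)
    depth = np.asarray(config.lambda_reorg) / config.polarization_scale
    return np.asarray(base_energies) - depth * new_qbar, new_qbar


def apply_decoherence(
    rho: np.ndarray, dt_fs: float, decoherence_time_fs: float | None
) -> np.ndarray:
    """Damp coherences by e^(−dt/τ_d), preserving the diagonal exactly."""
    if decoherence_time_fs is None or np.isinf(decoherence_time_fs):
        return rho
    factor = np.exp(-dt_fs / decoherence_time_fs)
    damped = rho * factor
    np.fill_diagonal(damped, np.diag(rho))
    # diagonal is untouched, so the trace (= 1) is preserved; renormalize
    # defensively against accumulated floating-point drift
    return damped / np.trace(damped).real


def run_trajectory(
    H0: CTHamiltonian,
    fluct: FluctuationModel,
    config: PropagationConfig,
    initial_site: str = "A",
) -> OccupationTrajectory:
    """Propagate one stochastic hole trajectory; deterministic given a seed.

    The wavefunction starts fully localized on ``initial_site`` and is
    stepped with the exact propagator of the instantaneous Hamiltonian
    (static couplings + OU noise − charge-response stabilization).
    Decoherence acts as stochastic localization: with probability
    1 − e^(−dt/τ_d) per step the wavefunction collapses onto a single site
    drawn from the instantaneous occupations, which leaves the ensemble-mean
    occupations unbiased while keeping each trajectory localized between
    hops.
    """
    n = len(H0.sites)
    for s in H0.sites:
        if s.role == "cofactor" or s.residue_name.upper() == "FAD":
            raise InputError(
                f"site {s.id!r} is a cofactor; only oxidisable sites belong "
                "in the propagated subspace"
            )
    if len(fluct.site_sd) != n:
        raise InputError("fluctuation model size does not match Hamiltonian")
    if len(config.lambda_reorg) != n:
        raise InputError("lambda_reorg size does not match Hamiltonian")
    init = H0.index(initial_site)

    rng = np.random.default_rng(config.seed)
    dt_ps = config.dt_fs * PS_PER_FS
    n_steps = int(round(config.total_time_ps / dt_ps))
    stride = max(1, int(round(config.output_dt_ps / dt_ps)))

    # environment-induced terms are screened by the polarization scale
    site_noise = np.stack([
        sample_ou(sd / config.polarization_scale, ct, config.dt_fs, n_steps, rng)
        for sd, ct in zip(fluct.site_sd, fluct.site_corr_time_ps)
    ])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if H0.matrix[i, j] != 0.0]
    if fluct.coupling_sd > 0:
        coupling_noise = {
            p: sample_ou(fluct.coupling_sd, fluct.coupling_corr_time_ps,
                         config.dt_fs, n_steps, rng)
            for p in pairs
        }
    else:
        coupling_noise = {}

    base = H0.matrix.copy()
    base_diag = np.diag(base).copy()
    psi = np.zeros(n, dtype=complex)
    psi[init] = 1.0
    qbar = np.zeros(n)

    if config.decoherence_time_fs is None:
        collapse = np.zeros(n_steps, dtype=bool)
    else:
        p_collapse = 1.0 - np.exp(-config.dt_fs / config.decoherence_time_fs)
        collapse = rng.uniform(size=n_steps) < p_collapse
    site_draws = rng.uniform(size=n_steps)

    times = [0.0]
    occs = [np.abs(psi) ** 2]
    h = base.copy()
    diag_idx = np.diag_indices(n)
    # inlined charge response (same update as apply_charge_response)
    alpha = 1.0 - np.exp(-dt_ps / config.solvent_relax_time_ps)
    depth = np.asarray(config.lambda_reorg) / config.polarization_scale
    phase_scale = -1j * dt_ps / HBAR_EV_PS
    eigh = np.linalg.eigh
    for k in range(n_steps):
        occ = (psi.real**2 + psi.imag**2)
        qbar = qbar + alpha * (occ - qbar)
        h[diag_idx] = base_diag + site_noise[:, k] - depth * qbar
        for (i, j), series in coupling_noise.items():
            h[i, j] = h[j, i] = base[i, j] + series[k]
        w, v = eigh(h)
        psi = (v * np.exp(phase_scale * w)) @ (v.T @ psi)
        psi /= np.sqrt(np.sum(psi.real**2 + psi.imag**2))
        if collapse[k]:
            occ = psi.real**2 + psi.imag**2
            site = int(np.searchsorted(np.cumsum(occ), site_draws[k] * occ.sum()))
            psi = np.zeros(n, dtype=complex)
            psi[site] = 1.0
        if (k + 1) % stride == 0:
            times.append((k + 1) * dt_ps)
            occs.append(psi.real**2 + psi.imag**2)

    occ = np.clip(np.asarray(occs), 0.0, None)
    occ /= occ.sum(axis=1, keepdims=True)
    return OccupationTrajectory(
        time_ps=np.asarray(times),
        occupations=occ,
        site_ids=H0.site_ids,
        metadata={
            "seed": config.seed,
            "initial_site": initial_site,
            "dt_fs": config.dt_fs,
        },
    )


def ensemble_average(
    trajectories: Sequence[OccupationTrajectory],
) -> OccupationEnsemble:
    """Pointwise mean and standard deviation over trajectories."""
    if not trajectories:
        raise InputError("need at least one trajectory")
    ref = trajectories[0]
    for tr in trajectories[1:]:
        if tr.time_ps.shape != ref.time_ps.shape or not np.allclose(
            tr.time_ps, ref.time_ps
        ):
            raise InputError("trajectories must share one time grid")
        if tr.site_ids != ref.site_ids:
            raise InputError("trajectories must share site ids")
    stack = np.stack([tr.occupations for tr in trajectories])
    return OccupationEnsemble(
        time_ps=ref.time_ps.copy(),
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=0),
        n_replicates=len(trajectories),
        site_ids=ref.site_ids,
    )
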