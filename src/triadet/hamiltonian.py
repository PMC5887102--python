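"""Parameterized charge-transfer Hamiltonians over a small set of hole sites.

A charge-transfer (CT) Hamiltonian collects, for an ordered list of redox
sites (the FAD cofactor and the aromatic side chains of the transfer triad),
the site energies on the diagonal and the electronic couplings on the
off-diagonal, all in eV.  Site energies act as in-protein proxies for the
residues' ionization potentials; couplings control transfer probability and
enter Marcus theory as the rate prefactor.

The matrix elements themselves are *inputs* here (tabulated or generated);
no electronic-structure calculation is performed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import HBAR_EV_PS, KB_EV_PER_K, PS_PER_NS
from .errors import InputError

__all__ = [
    "ChargeSite",
    "CTHamiltonian",
    "ChemicalData",
    "GAS_PHASE_IP_EV",
    "assemble_hamiltonian",
    "apply_shift",
    "energy_gap",
    "marcus_rate",
]

SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class ChargeSite:
    """One hole-carrying site (residue side chain or cofactor ring).

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"FAD"``, ``"A"``, ``"B"``, ``"C"``.
    residue_name : str
        Chemical identity (``"TYR"``, ``"TRP"``, ``"PHE"``, ``"FAD"``, ...).
    role : str
        One of ``donor``, ``bridge``, ``acceptor``, ``cofactor``.
    mean_energy : float
        Mean site energy in eV.
    energy_sd : float
        Thermal spread of the site energy in eV (non-negative).
    shift : float
        Additive chemistry-dependent correction in eV (default 0); the
        diagonal of the Hamiltonian carries ``mean_energy + shift``.
    """

    id: str
    mean_energy: float
    residue_name: str = "TRP"
    role: str = "bridge"
    energy_sd: float = 0.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_sd < 0:
            raise InputError(f"energy_sd must be >= 0, got {self.energy_sd}")


@dataclass(frozen=True)
class ChemicalData:
    """Gas-phase ionization potentials (eV) keyed by residue name."""

    ip_ev: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.ip_ev.items():
            if not value > 0:
                raise InputError(f"IP for {name} must be > 0, got {value}")

    def ip(self, residue_name: str) -> float:
        try:
            return self.ip_ev[residue_name.upper()]
        except KeyError:
            raise InputError(f"no ionization potential tabulated for {residue_name!r}")

    def ip_difference(self, a: str, b: str) -> float:
        """IP(a) − IP(b) in eV."""
        return self.ip(a) - self.ip(b)


#: Gas-phase ionization potentials (eV) of the FAD isoalloxazine ring and the
#: side chains considered at the first triad position.
GAS_PHASE_IP_EV = ChemicalData({"FAD": 8.05, "TYR": 8.15, "TRP": 7.54, "PHE": 8.84})


@dataclass(frozen=True)
class CTHamiltonian:
    """Symmetric site-energy / coupling matrix over an ordered site list.

    ``matrix[i, i] = sites[i].mean_energy + sites[i].shift`` (eV) and
    ``matrix[i, j]`` is the electronic coupling between sites i and j (eV).
    """

    sites: tuple[ChargeSite, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.sites)
        ids = [s.id for s in self.sites]
        if len(set(ids)) != n:
            raise InputError(f"duplicate site ids: {ids}")
        if m.shape != (n, n):
            raise InputError(f"matrix shape {m.shape} does not match {n} sites")
        if not np.allclose(m, m.T, atol=SYMMETRY_TOL, rtol=0):
            raise InputError("Hamiltonian matrix must be symmetric (<= 1e-12 eV)")
        diag = np.array([s.mean_energy + s.shift for s in self.sites])
        if not np.allclose(np.diag(m), diag, atol=1e-9, rtol=0):
            raise InputError("diagonal must equal mean_energy + shift of each site")

    # -- lookups ---------------------------------------------------------
    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sites)

    def index(self, site_id: str) -> int:
        try:
            return self.site_ids.index(site_id)
        except ValueError:
            raise InputError(f"unknown site id {site_id!r}; known: {self.site_ids}")

    def site(self, site_id: str) -> ChargeSite:
        return self.sites[self.index(site_id)]

    def coupling(self, i: str, j: str) -> float:
        """Electronic coupling between two sites in eV."""
        return float(self.matrix[self.index(i), self.index(j)])

    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix).copy()

    # -- I/O -------------------------------------------------------------
    def to_dict(self) -> dict:
        sites = [
            {
                "id": s.id,
                "residue": s.residue_name,
                "role": s.role,
                "mean_energy_eV": s.mean_energy,
                "energy_sd_eV": s.energy_sd,
                "shift_eV": s.shift,
            }
            for s in self.sites
        ]
        couplings = []
        n = len(self.sites)
        for i in range(n):
            for j in range(i + 1, n):
                if self.matrix[i, j] != 0.0:
                    couplings.append(
                        {"i": self.sites[i].id, "j": self.sites[j].id,
                         "value_eV": float(self.matrix[i, j])}
                    )
        return {"sites": sites, "couplings": couplings}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CTHamiltonian":
        sites = [
            ChargeSite(
                id=s["id"],
                residue_name=s.get("residue", "TRP"),
                role=s.get("role", "bridge"),
                mean_energy=s["mean_energy_eV"],
                energy_sd=s.get("energy_sd_eV", 0.0),
                shift=s.get("shift_eV", 0.0),
            )
            for s in data["sites"]
        ]
        couplings = {
            (c["i"], c["j"]): c["value_eV"] for c in data.get("couplings", [])
        }
        return assemble_hamiltonian(sites, couplings)

    @classmethod
    def from_json(cls, path) -> "CTHamiltonian":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def matrix_to_csv(self, path) -> None:
        """Export the full matrix with a site-id header row/column."""
        pd.DataFrame(self.matrix, index=self.site_ids,
                     columns=self.site_ids).to_csv(path)


def assemble_hamiltonian(
    sites: Iterable[ChargeSite],
    couplings: Mapping[tuple[str, str], float] | None = None,
) -> CTHamiltonian:
    """Build a CT Hamiltonian from sites and a pairwise coupling table.

    Unspecified pairs get coupling 0.  Coupling keys must reference two
    distinct known site ids; both orderings of a pair refer to the same
    symmetric element.
    """
    sites = tuple(sites)
    ids = [s.id for s in sites]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate site ids: {ids}")
    index = {sid: k for k, sid in enumerate(ids)}
    n = len(sites)
    m = np.zeros((n, n))
    m[np.diag_indices(n)] = [s.mean_energy + s.shift for s in sites]
    for (a, b), value in (couplings or {}).items():
        if a not in index:
            raise InputError(f"unknown site id {a!r} in coupling key ({a}, {b})")
        if b not in index:
            raise InputError(f"unknown site id {b!r} in coupling key ({a}, {b})")
        if a == b:
            raise InputError(f"coupling key ({a}, {b}) must reference distinct sites")
        m[index[a], index[b]] = value
        m[index[b], index[a]] = value
    return CTHamiltonian(sites=sites, matrix=m)


def apply_shift(H: CTHamiltonian, shifts: Mapping[str, float]) -> CTHamiltonian:
    """Add chemistry-dependent corrections to the diagonal.

    Each site's diagonal entry moves by ``shifts[residue_name]`` (0 when the
    residue name is absent from the table); couplings are untouched.
    """
    new_sites = tuple(
        replace(s, shift=s.shift + shifts.get(s.residue_name, 0.0)) for s in H.sites
    )
    m = H.matrix.copy()
    for k, s in enumerate(H.sites):
        m[k, k] += shifts.get(s.residue_name, 0.0)
    return CTHamiltonian(sites=new_sites, matrix=m)


def energy_gap(H: CTHamiltonian, donor_id: str, acceptor_id: str) -> float:
    """Diagonal energy difference ε_acceptor − ε_donor in eV.

    With site energies entered on a hole (ionization-potential-like) scale,
    a negative gap is downhill for the transferred hole.
    """
    return float(H.matrix[H.index(acceptor_id), H.index(acceptor_id)]
                 - H.matrix[H.index(donor_id), H.index(donor_id)])


def marcus_rate(
    delta_g: float,
    lambda_reorg: float,
    coupling: float,
    temperature: float = 300.0,
) -> float:
    """Non-adiabatic Marcus rate in ns^-1.

    k = (2π/ħ) |H|² (4π λ k_B T)^(−1/2) exp(−(ΔG + λ)² / (4 λ k_B T))

    with ΔG, λ and the coupling H in eV and the temperature in K.  The rate
    is maximal at ΔG = −λ (activationless transfer) and scales with |H|².
    """
    if not lambda_reorg > 0:
        raise InputError(f"lambda_reorg must be > 0, got {lambda_reorg}")
    if not temperature > 0:
        raise InputError(f"temperature must be > 0, got {temperature}")
    kbt = KB_EV_PER_K * temperature
    prefactor = (2.0 * math.pi / HBAR_EV_PS) * coupling**2
    fc = (4.0 * math.pi * lambda_reorg * kbt) ** -0.5 * math.exp(
        -((delta_g + lambda_reorg) ** 2) / (4.0 * lambda_reorg * kbt)
    )
    return prefactor * fc * PS_PER_NS  # ps^-1 -> ns^-1
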