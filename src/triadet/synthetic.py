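"""Synthetic inputs with known ground truth for every pipeline stage.

These generators stand in for the QM/MM trajectory ensembles and the
spectrophotometer data that the analysis normally consumes: occupation
ensembles under the three-state hopping scheme, photoreduction absorbance
traces, fluctuating-Hamiltonian parameter sets for the PhrB wild type and
the two Trp-rotamer variants of the Y391W mutant, and toy solvation
geometries with known radial structure.  Every generator records its ground
truth in the output metadata so recovery can be tested automatically.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import InputError
from .hamiltonian import ChargeSite, CTHamiltonian, assemble_hamiltonian
from .kinetics import (OccupationEnsemble, RateSet, gillespie,
                       occupations_on_grid, propagate_master)
from .photoreduction import AbsorbanceSeries
from .propagation import FluctuationModel, OccupationTrajectory
from .structure import StructureFrame

__all__ = [
    "RATE_PRESETS",
    "SYSTEM_PRESETS",
    "gen_occupation_ensemble",
    "gen_absorbance",
    "gen_fluctuating_system",
    "gen_solvation_structure",
    "write_metadata",
]

#: Hole-transfer rate constants (ns^-1) of the three-state chain for the
#: PhrB wild type and the proximal/distal Trp rotamers of the Y391W mutant.
RATE_PRESETS: dict[str, RateSet] = {
    "PhrB-WT": RateSet(870.0, 193.0, 199.0, 25.0),
    "Y391Wp": RateSet(63.0, 66.0, 124.0, 20.0),
    "Y391Wd": RateSet(237.0, 256.0, 231.0, 36.0),
}

# Parameter presets for the fluctuating 3-site (A, B, C) Hamiltonian.
# Site energies (eV): Trp sites sit near -5.8 eV, the Tyr at site A near
# -6.3 eV.  B-C couplings: 4.15 meV for the wild type (centre of the quoted
# 4.1-4.2 meV range); 9.0 / 7.0 meV for the proximal / distal Y391W rotamer,
# assigned by their B-C distance ordering (shorter distance, larger
# coupling).  A-B couplings are not reported numerically: 4 meV for WT and
# twice that for the Y391W rotamers (couplings roughly double on Tyr->Trp
# substitution).  In the distal rotamer site A sits 0.08 eV closer to B than
# in the proximal one.  Energy spreads (0.15 eV, 0.1 ps correlation) are
# typical thermal site-energy fluctuations in these proteins.
_DEFAULT_SD = 0.15
_DEFAULT_CORR_PS = 0.1
SYSTEM_PRESETS: dict[str, dict] = {
    "PhrB-WT": {
        "energies": {"A": -6.3, "B": -5.8, "C": -5.8},
        "residues": {"A": "TYR", "B": "TRP", "C": "TRP"},
        "couplings_mev": {("A", "B"): 4.0, ("B", "C"): 4.15},
    },
    "Y391Wp": {
        "energies": {"A": -5.72, "B": -5.8, "C": -5.8},
        "residues": {"A": "TRP", "B": "TRP", "C": "TRP"},
        "couplings_mev": {("A", "B"): 8.0, ("B", "C"): 9.0},
    },
    "Y391Wd": {
        "energies": {"A": -5.8, "B": -5.8, "C": -5.8},
        "residues": {"A": "TRP", "B": "TRP", "C": "TRP"},
        "couplings_mev": {("A", "B"): 8.0, ("B", "C"): 7.0},
    },
}


def gen_occupation_ensemble(
    rates: RateSet,
    n: int,
    tgrid_ps: np.ndarray,
    mode: str = "gillespie",
    noise_sd: float = 0.0,
    seed: int | None = None,
    p0: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> tuple[OccupationEnsemble, list[OccupationTrajectory]]:
    """Synthetic occupation ensemble under the three-state hopping scheme.

    ``mode="gillespie"`` averages ``n`` stochastic indicator trajectories
    (also returned individually); ``mode="ode"`` perturbs the exact
    master-equation mean with i.i.d. Gaussian noise truncated to [0, 1] and
    renormalized.  Ground-truth rates are recorded in the metadata.
    """
    if n < 1:
        raise InputError("need n >= 1 replicates")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    t = np.asarray(tgrid_ps, dtype=float)
    rng = np.random.default_rng(seed)
    truth = {
        "rates_ns": {"k12": rates.k12, "k21": rates.k21,
                     "k23": rates.k23, "k32": rates.k32},
        "mode": mode,
        "noise_sd": noise_sd,
        "seed": seed,
        "n_replicates": n,
    }
    trajectories: list[OccupationTrajectory] = []
    if mode == "gillespie":
        occs = np.empty((n, t.size, 3))
        for r in range(n):
            bp, states = gillespie(rates, float(t[-1]) + 1e-9, rng)
            occ = occupations_on_grid(bp, states, t)
            occs[r] = occ
            trajectories.append(OccupationTrajectory(
                time_ps=t.copy(), occupations=occ, site_ids=("A", "B", "C"),
                metadata={"replicate": r, **truth},
            ))
        mean, sd = occs.mean(axis=0), occs.std(axis=0, ddof=0)
        if noise_sd > 0:
            mean = np.clip(mean + rng.normal(0, noise_sd, mean.shape), 0, 1)
            mean /= mean.sum(axis=1, keepdims=True)
    elif mode == "ode":
        mean = propagate_master(rates, p0, t)
        if noise_sd > 0:
            mean = np.clip(mean + rng.normal(0, noise_sd, mean.shape), 0, 1)
            mean /= mean.sum(axis=1, keepdims=True)
        sd = np.full_like(mean, noise_sd)
    else:
        raise InputError(f"unknown mode {mode!r}; use 'gillespie' or 'ode'")
    ensemble = OccupationEnsemble(
        time_ps=t, mean=mean, sd=sd, n_replicates=n, metadata=truth
    )
    return ensemble, trajectories


def gen_absorbance(
    tau_450: float = 36.0,
    tau_rise_580: float = 6.0,
    tau_decay_580: float = 110.0,
    amp_450: float = 0.8,
    offset_450: float = 0.2,
    amp_580: float = 0.05,
    offset_580: float = 0.01,
    a280: float = 0.5,
    tgrid_min: np.ndarray | None = None,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> AbsorbanceSeries:
    """Synthetic photoreduction trace with multiplicative Gaussian noise.

    A450 = offset + amp·e^(−t/τ450); the 580 nm excess follows a difference
    of exponentials, so its t = 0 excess is exactly 0; A280 is constant.
    Defaults mirror the wild-type kinetics (36 min decay; 6 / 110 min
    rise / decay).
    """
    for tau in (tau_450, tau_rise_580, tau_decay_580):
        if not tau > 0:
            raise InputError("time constants must be > 0")
    if tgrid_min is None:
        tgrid_min = np.linspace(0.0, 90.0, 19)
    t = np.asarray(tgrid_min, dtype=float)
    rng = np.random.default_rng(seed)
    a450 = offset_450 + amp_450 * np.exp(-t / tau_450)
    a580 = offset_580 + amp_580 * (
        np.exp(-t / tau_decay_580) - np.exp(-t / tau_rise_580)
    )
    a280_series = np.full_like(t, a280)
    if noise_sd > 0:
        a450 = a450 * (1.0 + rng.normal(0, noise_sd, t.size))
        a580 = a580 * (1.0 + rng.normal(0, noise_sd, t.size))
        a280_series = a280_series * (1.0 + rng.normal(0, noise_sd, t.size))
    return AbsorbanceSeries(
        time_min=t, a450=a450, a580=a580, a280=a280_series,
        metadata={
            "tau_450": tau_450, "tau_rise_580": tau_rise_580,
            "tau_decay_580": tau_decay_580, "amp_450": amp_450,
            "offset_450": offset_450, "amp_580": amp_580,
            "offset_580": offset_580, "a280": a280,
            "noise_sd": noise_sd, "seed": seed,
        },
    )


def gen_fluctuating_system(
    preset: str = "PhrB-WT",
    overrides: dict | None = None,
    sd_ev: float = _DEFAULT_SD,
    corr_time_ps: float = _DEFAULT_CORR_PS,
) -> tuple[CTHamiltonian, FluctuationModel]:
    """Named 3-site (A, B, C) parameter set with shallow overrides.

    Overrides replace individual entries, e.g.
    ``{"energies": {"A": -6.0}, "couplings_mev": {("A", "B"): 5.0}}``.
    """
    if preset not in SYSTEM_PRESETS:
        raise InputError(
            f"unknown preset {preset!r}; known: {sorted(SYSTEM_PRESETS)}"
        )
    spec = {k: dict(v) for k, v in SYSTEM_PRESETS[preset].items()}
    for key, sub in (overrides or {}).items():
        if key not in spec:
            raise InputError(f"unknown override section {key!r}")
        spec[key].update(sub)
    sites = [
        ChargeSite(id=sid, mean_energy=spec["energies"][sid],
                   residue_name=spec["residues"][sid],
                   role=("donor" if sid == "A" else
                         "acceptor" if sid == "C" else "bridge"),
                   energy_sd=sd_ev)
        for sid in ("A", "B", "C")
    ]
    couplings = {pair: mev * 1e-3 for pair, mev in spec["couplings_mev"].items()}
    ham = assemble_hamiltonian(sites, couplings)
    fluct = FluctuationModel(
        site_sd=(sd_ev,) * 3, site_corr_time_ps=(corr_time_ps,) * 3
    )
    return ham, fluct


def gen_solvation_structure(
    kind: str = "uniform",
    n_probes: int = 1000,
    box: float = 30.0,
    shell_radius: float = 5.0,
    shell_width: float = 0.2,
    seed: int | None = None,
) -> StructureFrame:
    """Toy solvation geometry: water oxygens around a central carbon atom.

    ``kind="uniform"`` scatters probes uniformly in a periodic cubic box
    (flat g(r)); ``kind="shell"`` places them on a Gaussian shell of the
    given radius and width around the centre (g(r) peak at the radius).
    The centre atom is residue 1 ("CTR", atom "C") at the box centre.
    """
    if n_probes < 1:
        raise InputError("need n_probes >= 1")
    rng = np.random.default_rng(seed)
    centre = np.full(3, box / 2.0)
    if kind == "uniform":
        coords = rng.uniform(0.0, box, size=(n_probes, 3))
    elif kind == "shell":
        direction = rng.standard_normal((n_probes, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radii = rng.normal(shell_radius, shell_width, n_probes)
        coords = centre + direction * radii[:, None]
    else:
        raise InputError(f"unknown kind {kind!r}; use 'uniform' or 'shell'")
    n = n_probes + 1
    return StructureFrame(
        element=np.array(["C"] + ["O"] * n_probes),
        atom_name=np.array(["C"] + ["O"] * n_probes),
        res_name=np.array(["CTR"] + ["HOH"] * n_probes),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        coords=np.vstack([centre, coords]),
        mass=np.array([12.011] + [15.999] * n_probes),
        box=np.full(3, box),
    )


def write_metadata(metadata: dict, path) -> None:
    """Write a ground-truth sidecar JSON next to a generated dataset."""
    def _default(obj):
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return list(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, default=_default)
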