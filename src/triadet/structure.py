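"""Structural descriptors: centre-of-mass distances, water RDFs, H-bonds.

Coordinates are in Å with 1-based author residue numbering.  PDB files are
read through biotite (multi-MODEL files become multiple frames; for
alternate locations the highest-occupancy conformer is kept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, GeometryError, InputError

__all__ = [
    "StructureFrame",
    "SiteSelection",
    "RDFResult",
    "read_pdb",
    "write_pdb",
    "com_distance",
    "rdf",
    "hbond_geometry",
]

WATER_RES_NAMES = ("HOH", "WAT", "SOL", "TIP3")


@dataclass
class StructureFrame:
    """Atomic coordinates with residue labels (one model of a structure)."""

    element: np.ndarray        # str per atom
    atom_name: np.ndarray      # str per atom
    res_name: np.ndarray       # str per atom
    res_id: np.ndarray         # int per atom, 1-based author numbering
    chain_id: np.ndarray       # str per atom
    coords: np.ndarray         # (n, 3) Å
    mass: np.ndarray           # Da per atom
    box: np.ndarray | None = None   # (3,) orthorhombic edge lengths in Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise InputError("coordinates must be finite")
        if np.any(self.mass <= 0):
            raise InputError("atom masses must be > 0")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_atom_array(cls, atoms: struc.AtomArray) -> "StructureFrame":
        masses = np.array([
            struc_info.mass(el.capitalize()) if el else 1.0
            for el in atoms.element
        ])
        box = None
        if atoms.box is not None:
            box = np.diag(np.asarray(atoms.box, dtype=float))
            if not np.any(box > 0):
                box = None
        return cls(
            element=np.asarray(atoms.element),
            atom_name=np.asarray(atoms.atom_name),
            res_name=np.asarray(atoms.res_name),
            res_id=np.asarray(atoms.res_id, dtype=int),
            chain_id=np.asarray(atoms.chain_id),
            coords=np.asarray(atoms.coord, dtype=float),
            mass=masses,
            box=box,
        )

    def to_atom_array(self) -> struc.AtomArray:
        atoms = struc.AtomArray(self.n_atoms)
        atoms.coord = self.coords.astype(np.float32)
        atoms.element = self.element
        atoms.atom_name = self.atom_name
        atoms.res_name = self.res_name
        atoms.res_id = self.res_id
        atoms.chain_id = self.chain_id
        atoms.hetero = np.isin(self.res_name, WATER_RES_NAMES)
        if self.box is not None:
            atoms.box = np.diag(self.box).astype(np.float32)
        return atoms


@dataclass(frozen=True)
class SiteSelection:
    """Named set of atoms given as (residue number, atom name) pairs."""

    name: str
    atoms: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple((int(r), a) for r, a in self.atoms))
        if not self.atoms:
            raise InputError(f"selection {self.name!r} is empty")

    def resolve(self, frame: StructureFrame) -> np.ndarray:
        idx = []
        for res, name in self.atoms:
            hits = np.nonzero((frame.res_id == res) & (frame.atom_name == name))[0]
            idx.extend(hits.tolist())
        if not idx:
            raise InputError(
                f"selection {self.name!r} resolves to no atoms in this frame"
            )
        return np.asarray(sorted(set(idx)), dtype=int)


@dataclass
class RDFResult:
    """Radial distribution g(r) and cumulative probe count N(r)."""

    r: np.ndarray        # bin centres, Å
    g: np.ndarray        # dimensionless
    n_cum: np.ndarray    # mean cumulative count within r

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise InputError("g(r) must be non-negative")
        if np.any(np.diff(self.n_cum) < -1e-9):
            raise InputError("N(r) must be non-decreasing")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> list[StructureFrame]:
    """Read a PDB file into one frame per MODEL.

    Alternate locations keep the highest-occupancy conformer; coordinates
    are in Å and residue numbers follow the author (1-based) numbering.
    """
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:
        line = _offending_line(path)
        suffix = f" (near line {line})" if line else ""
        raise FormatError(f"cannot parse PDB file {path}{suffix}: {exc}") from exc
    frames = []
    for model in stack:
        frames.append(StructureFrame.from_atom_array(model))
    return frames


def _offending_line(path) -> int | None:
    """Best-effort location of the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def write_pdb(frame: StructureFrame, path) -> None:
    """Write a frame as a PDB file."""
    pdb = PDBFile()
    pdb.set_structure(frame.to_atom_array())
    pdb.write(path)


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def _centroid(frame: StructureFrame, sel: SiteSelection, mass_weighted: bool) -> np.ndarray:
    idx = sel.resolve(frame)
    if mass_weighted:
        w = frame.mass[idx]
        return (frame.coords[idx] * w[:, None]).sum(axis=0) / w.sum()
    return frame.coords[idx].mean(axis=0)


def com_distance(
    frames: StructureFrame | Sequence[StructureFrame],
    sel1: SiteSelection,
    sel2: SiteSelection,
    mass_weighted: bool = True,
) -> float:
    """Distance (Å) between the (mass-weighted) centroids of two selections;
    the per-frame mean when several frames are given."""
    if isinstance(frames, StructureFrame):
        frames = [frames]
    dists = [
        float(np.linalg.norm(_centroid(f, sel1, mass_weighted)
                             - _centroid(f, sel2, mass_weighted)))
        for f in frames
    ]
    return float(np.mean(dists))


def _min_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def _probe_mask(frame: StructureFrame, probe_atom_name: str,
                probe_res_names: tuple[str, ...] | None) -> np.ndarray:
    mask = frame.atom_name == probe_atom_name
    if probe_res_names is not None:
        mask &= np.isin(frame.res_name, probe_res_names)
    return mask


def rdf(
    frames: StructureFrame | Sequence[StructureFrame],
    center: SiteSelection,
    probe_atom_name: str = "O",
    probe_res_names: tuple[str, ...] | None = WATER_RES_NAMES,
    dr: float = 0.1,
    r_max: float = 10.0,
    mode: str = "min",
) -> RDFResult:
    """Radial distribution of probe atoms around a selection.

    The probe-to-center distance is the minimum over the selection's atoms
    (``mode="min"``) or the distance to the mass-weighted centroid
    (``mode="com"``).  g(r) is normalized by ideal-gas shell counts at the
    frame's mean probe density (box volume when periodic, the r_max sphere
    otherwise); N(r) is the raw mean cumulative count.
    """
    if isinstance(frames, StructureFrame):
        frames = [frames]
    if not frames:
        raise InputError("need at least one frame")
    if mode not in ("min", "com"):
        raise InputError(f"mode must be 'min' or 'com', got {mode!r}")
    edges = np.arange(0.0, r_max + dr, dr)
    r_centres = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(r_centres.size)
    densities = []
    for frame in frames:
        mask = _probe_mask(frame, probe_atom_name, probe_res_names)
        if not mask.any():
            raise InputError(
                f"no probe atoms named {probe_atom_name!r} in frame"
            )
        probes = frame.coords[mask]
        if mode == "com":
            ref = _centroid(frame, center, mass_weighted=True)[None, :]
        else:
            ref = frame.coords[center.resolve(frame)]
        delta = probes[:, None, :] - ref[None, :, :]
        delta = _min_image(delta, frame.box)
        dist = np.sqrt((delta**2).sum(axis=2)).min(axis=1)
        hist += np.histogram(dist, bins=edges)[0]
        if frame.box is not None:
            volume = float(np.prod(frame.box))
            densities.append(probes.shape[0] / volume)
        else:
            inside = int((dist <= r_max).sum())
            densities.append(inside / (4.0 / 3.0 * math.pi * r_max**3))
    n_frames = len(frames)
    mean_counts = hist / n_frames
    rho = float(np.mean(densities))
    shell_volumes = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(rho > 0, mean_counts / (rho * shell_volumes), 0.0)
    return RDFResult(r=r_centres, g=g, n_cum=np.cumsum(mean_counts))


def _resolve_atom(frame: StructureFrame, atom) -> int:
    if isinstance(atom, (int, np.integer)):
        return int(atom)
    res, name = atom
    sel = SiteSelection("atom", ((res, name),))
    idx = sel.resolve(frame)
    if idx.size != 1:
        raise InputError(f"atom spec {atom!r} resolves to {idx.size} atoms")
    return int(idx[0])


def hbond_geometry(
    frame: StructureFrame,
    donor,
    hydrogen,
    acceptor,
    d_max: float = 3.5,
    angle_min: float = 135.0,
) -> tuple[bool, float, float]:
    """Geometric hydrogen-bond test.

    True iff the donor–acceptor distance is ≤ ``d_max`` Å and the D–H···A
    angle is ≥ ``angle_min`` degrees.  Atoms may be given as indices or
    (residue number, atom name) pairs; returns (is_hbond, distance, angle).
    """
    d, h, a = (_resolve_atom(frame, x) for x in (donor, hydrogen, acceptor))
    if len({d, h, a}) != 3:
        raise InputError("donor, hydrogen and acceptor must be distinct atoms")
    rd, rh, ra = frame.coords[d], frame.coords[h], frame.coords[a]
    v1, v2 = rd - rh, ra - rh
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9 or np.linalg.norm(rd - ra) < 1e-9:
        raise GeometryError("coincident atoms in hydrogen-bond geometry")
    cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    distance = float(np.linalg.norm(rd - ra))
    return (distance <= d_max and angle >= angle_min, distance, angle)
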