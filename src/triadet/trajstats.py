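"""Transfer statistics on thresholded occupation trajectories.

The hole is assigned to a site when that site's occupation exceeds 50%
(strictly); otherwise the state is "delocalized".  On the resulting label
sequence the module counts back-transfers ν (source → target transitions
whose target dwell exceeds a minimum of 0.5 ps) and the total qualifying
residence time τ on a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "DELOCALIZED",
    "StateSequence",
    "TransferStats",
    "assign_states",
    "count_back_transfers",
    "residence_time",
    "ensemble_stats",
]

DELOCALIZED = "delocalized"


@dataclass(frozen=True)
class StateSequence:
    """Piecewise-constant site labels: segment i spans
    [breakpoints[i], breakpoints[i+1]) ps."""

    breakpoints: tuple[float, ...]   # length n_segments + 1, first = 0
    labels: tuple[str, ...]          # length n_segments

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(bp) != len(self.labels) + 1:
            raise InputError("need len(labels)+1 breakpoints")
        if bp[0] != 0.0:
            raise InputError("first breakpoint must be 0")
        if np.any(np.diff(bp) <= 0):
            raise InputError("breakpoints must be strictly increasing")

    def durations(self) -> np.ndarray:
        return np.diff(np.asarray(self.breakpoints))


@dataclass(frozen=True)
class TransferStats:
    """Ensemble-average back-transfer count ν and residence time τ (ps)."""

    nu: float
    tau: float

    def __post_init__(self) -> None:
        if self.nu < 0 or self.tau < 0:
            raise InputError("nu and tau must be >= 0")


def assign_states(
    time_ps: np.ndarray,
    occupations: np.ndarray,
    site_ids: Sequence[str],
    threshold: float = 0.5,
) -> StateSequence:
    """Label each time point with the unique site whose occupation exceeds
    ``threshold`` strictly, else "delocalized", and merge runs into segments.

    Each sample represents one grid step, so the sequence extends one step
    beyond the last sample time.  The threshold must lie in (1/3, 1] for a
    3-site system so the labelled site is unique.
    """
    n_sites = occupations.shape[1]
    if not (1.0 / n_sites < threshold <= 1.0):
        raise InputError(
            f"threshold must lie in (1/{n_sites}, 1], got {threshold}"
        )
    time_ps = np.asarray(time_ps, dtype=float)
    occ = np.asarray(occupations, dtype=float)
    if occ.shape[0] != time_ps.size:
        raise InputError("occupations and time grid length mismatch")
    dt = time_ps[1] - time_ps[0] if time_ps.size > 1 else 1.0

    winners = np.argmax(occ, axis=1)
    above = occ[np.arange(occ.shape[0]), winners] > threshold
    labels_pt = [site_ids[w] if ok else DELOCALIZED
                 for w, ok in zip(winners, above)]

    breakpoints = [0.0]
    labels: list[str] = [labels_pt[0]]
    for i in range(1, len(labels_pt)):
        if labels_pt[i] != labels[-1]:
            labels.append(labels_pt[i])
            breakpoints.append(time_ps[i] - time_ps[0])
    breakpoints.append(time_ps[-1] - time_ps[0] + dt)
    return StateSequence(tuple(breakpoints), tuple(labels))


def coalesce(seq: StateSequence, gap_tol: float = 0.1) -> StateSequence:
    """Absorb delocalized segments no longer than ``gap_tol`` ps.

    A short delocalized gap between two dwells is bridged: its duration is
    credited to the merged dwell when both neighbours carry the same label,
    and to the following dwell when they differ (the transition survives).
    Leading/trailing short gaps attach to their single neighbour.  Adjacent
    same-label segments are merged.
    """
    bp = list(seq.breakpoints)
    labels = list(seq.labels)
    # drop short delocalized segments by merging their time into a neighbour
    changed = True
    while changed:
        changed = False
        for i, lab in enumerate(labels):
            dur = bp[i + 1] - bp[i]
            if lab == DELOCALIZED and dur <= gap_tol and len(labels) > 1:
                del labels[i]
                del bp[i + 1 if i + 1 < len(bp) - 1 else i]
                changed = True
                break
    # merge adjacent equal labels
    out_bp = [bp[0]]
    out_labels = [labels[0]]
    for i in range(1, len(labels)):
        if labels[i] == out_labels[-1]:
            continue
        out_labels.append(labels[i])
        out_bp.append(bp[i])
    out_bp.append(bp[-1])
    return StateSequence(tuple(out_bp), tuple(out_labels))


def count_back_transfers(
    seq: StateSequence,
    target: str = "A",
    source: str = "B",
    min_dwell: float = 0.5,
    gap_tol: float = 0.1,
    count_all: bool = False,
) -> int:
    """Count source → target transitions whose target dwell exceeds
    ``min_dwell`` ps (all transitions when ``count_all``).

    Delocalized gaps no longer than ``gap_tol`` between source and target do
    not break the transition.
    """
    for s in (target, source):
        if not s:
            raise InputError("empty site label")
    red = coalesce(seq, gap_tol)
    durations = red.durations()
    count = 0
    for i in range(1, len(red.labels)):
        if red.labels[i] == target and red.labels[i - 1] == source:
            if count_all or durations[i] > min_dwell:
                count += 1
    return count


def residence_time(
    seq: StateSequence,
    site: str = "A",
    min_dwell: float = 0.5,
    gap_tol: float = 0.1,
) -> float:
    """Total time (ps) spent in dwells on ``site`` longer than ``min_dwell``."""
    red = coalesce(seq, gap_tol)
    durations = red.durations()
    return float(sum(
        d for lab, d in zip(red.labels, durations)
        if lab == site and d > min_dwell
    ))


def ensemble_stats(
    sequences: Iterable[StateSequence],
    target: str = "A",
    source: str = "B",
    min_dwell: float = 0.5,
    gap_tol: float = 0.1,
) -> TransferStats:
    """Arithmetic means of ν and τ over an ensemble of sequences."""
    sequences = list(sequences)
    if not sequences:
        raise InputError("need at least one sequence")
    nus = [count_back_transfers(s, target, source, min_dwell, gap_tol)
           for s in sequences]
    taus = [residence_time(s, target, min_dwell, gap_tol) for s in sequences]
    return TransferStats(nu=float(np.mean(nus)), tau=float(np.mean(taus)))
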