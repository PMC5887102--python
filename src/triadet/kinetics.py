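"""Three-state hopping kinetics of the radical-pair chain RP-A ⇌ RP-B ⇌ RP-C.

The hole hops along a strict linear chain (no direct A–C rate) with four
rate constants k12, k21, k23, k32 in ns^-1.  The module provides the
master-equation solution, the closed-form stationary distribution, exact
stochastic (Gillespie) realizations, and weighted least-squares fitting of
the four rates to averaged occupation curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
import scipy.linalg

from .constants import PS_PER_NS
from .errors import FitError, InputError

__all__ = [
    "RateSet",
    "OccupationEnsemble",
    "RateFit",
    "rate_matrix",
    "propagate_master",
    "stationary",
    "gillespie",
    "occupations_on_grid",
    "fit_rates",
]

SITE_IDS = ("A", "B", "C")


@dataclass(frozen=True)
class RateSet:
    """Hole-transfer rate constants of the linear chain, in ns^-1."""

    k12: float
    k21: float
    k23: float
    k32: float

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k23", "k32"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.k12, self.k21, self.k23, self.k32])


@dataclass
class OccupationEnsemble:
    """Averaged per-site occupations on a uniform time grid (ps)."""

    time_ps: np.ndarray
    mean: np.ndarray                 # (n_times, 3)
    sd: np.ndarray | None = None     # (n_times, 3)
    n_replicates: int = 1
    site_ids: tuple[str, ...] = SITE_IDS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ps = np.asarray(self.time_ps, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.mean.shape != (self.time_ps.size, len(self.site_ids)):
            raise InputError("mean shape does not match grid / sites")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.mean.shape:
                raise InputError("sd shape does not match mean")
        steps = np.diff(self.time_ps)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
            raise InputError("time grid must be uniform")

    def to_csv(self, path) -> None:
        data = {"time_ps": self.time_ps}
        for k, sid in enumerate(self.site_ids):
            data[f"mean_{sid}"] = self.mean[:, k]
            data[f"sd_{sid}"] = (self.sd[:, k] if self.sd is not None
                                 else np.zeros_like(self.time_ps))
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccupationEnsemble":
        df = pd.read_csv(path)
        site_ids = tuple(c[len("mean_"):] for c in df.columns if c.startswith("mean_"))
        mean = df[[f"mean_{s}" for s in site_ids]].to_numpy()
        sd_cols = [f"sd_{s}" for s in site_ids]
        sd = df[sd_cols].to_numpy() if all(c in df.columns for c in sd_cols) else None
        return cls(time_ps=df["time_ps"].to_numpy(), mean=mean, sd=sd,
                   site_ids=site_ids)


@dataclass
class RateFit:
    """Result of fitting the four chain rates to occupation curves."""

    rates: RateSet
    residual_rms: float
    covariance: np.ndarray | None
    converged: bool
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise InputError("residual RMS must be >= 0")


def rate_matrix(rates: RateSet) -> np.ndarray:
    """Generator K (ps^-1) of dp/dt = K p for p = (p_A, p_B, p_C)."""
    k12, k21, k23, k32 = rates.as_array() / PS_PER_NS  # ns^-1 -> ps^-1
    return np.array(
        [
            [-k12, k21, 0.0],
            [k12, -(k21 + k23), k32],
            [0.0, k23, -k32],
        ]
    )


def _validate_p0(p0: Sequence[float]) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (3,) or np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-8:
        raise InputError("p0 must be 3 non-negative occupations summing to 1")
    return p0


def propagate_master(
    rates: RateSet, p0: Sequence[float], tgrid_ps: np.ndarray
) -> np.ndarray:
    """Occupations p(t) of the master equation on ``tgrid_ps`` (shape n×3).

    Solved by eigendecomposition of the generator (matrix exponential
    fallback when the eigenbasis is ill-conditioned); probability is
    conserved exactly by construction of K.
    """
    p0 = _validate_p0(p0)
    t = np.asarray(tgrid_ps, dtype=float)
    k = rate_matrix(rates)
    w, v = np.linalg.eig(k)
    if np.linalg.cond(v) < 1e10:
        c = np.linalg.solve(v, p0)
        occ = np.real(np.exp(np.outer(t, w)) * c @ v.T)
    else:  # defective generator: step with expm
        occ = np.empty((t.size, 3))
        for i, ti in enumerate(t):
            occ[i] = scipy.linalg.expm(k * ti) @ p0
    return np.clip(occ, 0.0, 1.0 + 1e-12)


def stationary(rates: RateSet) -> np.ndarray:
    """Closed-form stationary distribution of the linear chain.

    p_A : p_B : p_C = k21·k32 : k12·k32 : k12·k23 (detailed balance).
    """
    k12, k21, k23, k32 = rates.as_array()
    weights = np.array([k21 * k32, k12 * k32, k12 * k23])
    total = weights.sum()
    if total <= 0:
        raise InputError(
            "stationary state undefined: k12*k23 + k12*k32 + k21*k32 must be > 0"
        )
    return weights / total


def gillespie(
    rates: RateSet,
    total_time_ps: float,
    seed: int | np.random.Generator | None = None,
    initial_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic realization of the chain, starting in state A.

    Returns ``(breakpoints_ps, states)`` where segment i occupies state
    ``states[i]`` (0=A, 1=B, 2=C) on ``[breakpoints[i], breakpoints[i+1])``;
    the final breakpoint is ``total_time_ps``.
    """
    if not total_time_ps > 0:
        raise InputError("total_time must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = rates.as_array() / PS_PER_NS  # ps^-1
    # out-rates and destinations per state
    out = {0: [(k[0], 1)], 1: [(k[1], 0), (k[2], 2)], 2: [(k[3], 1)]}
    t, state = 0.0, initial_state
    breakpoints, states = [0.0], [state]
    while True:
        channels = out[state]
        total = sum(r for r, _ in channels)
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= total_time_ps:
            break
        u = rng.uniform(0, total)
        acc = 0.0
        for r, dest in channels:
            acc += r
            if u < acc:
                state = dest
                break
        breakpoints.append(t)
        states.append(state)
    breakpoints.append(total_time_ps)
    return np.asarray(breakpoints), np.asarray(states, dtype=int)


def occupations_on_grid(
    breakpoints: np.ndarray, states: np.ndarray, tgrid_ps: np.ndarray
) -> np.ndarray:
    """Indicator occupations (n×3) of a piecewise-constant state trajectory."""
    idx = np.searchsorted(breakpoints[1:-1], tgrid_ps, side="right")
    occ = np.zeros((len(tgrid_ps), 3))
    occ[np.arange(len(tgrid_ps)), states[idx]] = 1.0
    return occ


def fit_rates(
    ensemble: OccupationEnsemble,
    p0: Sequence[float] = (1.0, 0.0, 0.0),
    n_starts: int = 8,
    rate_bounds: tuple[float, float] = (1e-3, 1e5),
) -> RateFit:
    """Fit the four chain rates to the three mean-occupation curves.

    Weighted least squares (weights 1/sd when per-point SDs are provided,
    uniform otherwise) over ``n_starts`` log-spaced initializations of all
    four rates across [1, 10^4] ns^-1; the best converged start wins.
    Rates pinned at the lower bound are reported in ``diagnostics``.
    """
    if ensemble.time_ps.size < 10:
        raise InputError("need at least 10 time points to fit four rates")
    if len(ensemble.site_ids) != 3:
        raise InputError("rate fitting requires a 3-site ensemble")
    p0 = _validate_p0(p0)
    t = ensemble.time_ps
    y = ensemble.mean
    if ensemble.sd is not None and np.any(ensemble.sd > 0):
        # zero-SD points (e.g. indicator ensembles where all replicates
        # agree) carry no evidence of infinite precision: floor the SD at
        # the smallest positive value observed
        floor = float(np.min(ensemble.sd[ensemble.sd > 0]))
        weights = 1.0 / np.clip(ensemble.sd, floor, None)
    else:
        weights = np.ones_like(y)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        rs = RateSet(params["k12"].value, params["k21"].value,
                     params["k23"].value, params["k32"].value)
        return ((propagate_master(rs, p0, t) - y) * weights).ravel()

    best = None
    errors = []
    for start in np.logspace(0, 4, n_starts):
        params = lmfit.Parameters()
        for name in ("k12", "k21", "k23", "k32"):
            params.add(name, value=start, min=rate_bounds[0], max=rate_bounds[1])
        try:
            res = lmfit.minimize(residual, params, method="least_squares")
        except Exception as exc:  # pragma: no cover - numerical pathologies
            errors.append(f"start {start:g}: {exc}")
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("all fit starts failed: " + "; ".join(errors))

    fitted = RateSet(*(best.params[n].value for n in ("k12", "k21", "k23", "k32")))
    diagnostics = []
    for name in ("k12", "k21", "k23", "k32"):
        v = best.params[name].value
        if v <= rate_bounds[0] * 1.01:
            diagnostics.append(f"{name} pinned at lower bound ({v:g} ns^-1): "
                               "rate not identifiable from these curves")
        if v >= rate_bounds[1] * 0.99:
            diagnostics.append(f"{name} pinned at upper bound ({v:g} ns^-1)")
    resid = propagate_master(fitted, p0, t) - y
    return RateFit(
        rates=fitted,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        covariance=(np.asarray(best.covar) if best.covar is not None else None),
        converged=bool(best.success),
        diagnostics=diagnostics,
    )
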