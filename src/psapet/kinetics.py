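"""Saturable ligand-receptor compartmental models for flumazenil PET.

The target region is described by a two-tissue-compartment (2TC) model with a
free compartment and a saturable, specifically bound compartment.  Labelled
("hot") and unlabelled ("cold") ligand are chemically identical and therefore
share every rate constant; they interact only through competition for the
finite receptor pool ``b_max``.  For the hot species (starred) the state
equations are

    dF*/dt = K1·Cp*(t) − k2·F* − (kon/Vr)·F*·(Bmax − B* − B) + koff·B*
    dB*/dt = (kon/Vr)·F*·(Bmax − B* − B) − koff·B*

with the identical pair for the cold species driven by the cold plasma
concentration Cp(t).  A reference region devoid of specific binding is a
one-tissue-compartment (1TC) model, dC/dt = k1r·Cp*(t) − k2r·C.

All concentrations are in pmol/ml of tissue, times in minutes, and every
curve is assumed decay-corrected (so no physical-decay term appears).  There
is no fractional blood-volume term: the modelled signal is free + bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "DerivedConstants",
    "ReferenceParameters",
    "SimulationResult",
    "ReferenceSimulation",
    "TimeActivityCurve",
    "SimulationError",
    "derive_constants",
    "simulate_target_tac",
    "simulate_reference_tac",
    "frame_average",
    "occupancy_curve",
]

#: default solver tolerances (pmol/ml for atol)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10

#: ROI labels accepted on time-activity curves
ROI_LABELS = (
    "left hippocampus",
    "right hippocampus",
    "hippocampus",
    "cortex",
    "amygdala",
    "thalamus",
    "olive nucleus",
    "ventricles",
    "whole brain",
    "free",  # synthetic "true free" trajectory framed like a TAC
)


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or produces an invalid state."""


def _require_positive(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """Five identifiable constants of the saturable 2TC model.

    Attributes
    ----------
    b_max : receptor density available for binding, pmol/ml tissue.
    k1 : plasma-to-tissue transfer of free ligand, /min.
    k2 : tissue-to-plasma efflux of free ligand, /min.
    kon_vr : apparent association rate kon/Vr, ml·pmol⁻¹·min⁻¹.
    koff : dissociation rate from the receptor, /min.
    """

    b_max: float
    k1: float
    k2: float
    kon_vr: float
    koff: float

    def __post_init__(self) -> None:
        for name in ("b_max", "k1", "k2", "kon_vr", "koff"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class DerivedConstants:
    """Quantities derived from :class:`KineticParameters`.

    kd_vr is the apparent equilibrium dissociation constant koff/(kon/Vr)
    (pmol/ml); inv_kd_vr = 1/kd_vr is the apparent affinity (ml/pmol);
    dv1 = K1/k2 is the free-compartment distribution volume; bp = Bmax/KdVr
    is the binding potential.
    """

    kd_vr: float
    inv_kd_vr: float
    dv1: float
    bp: float


@dataclass(frozen=True)
class ReferenceParameters:
    """1TC reference-region constants (no specific binding)."""

    k1r: float
    k2r: float

    def __post_init__(self) -> None:
        _require_positive("k1r", self.k1r)
        _require_positive("k2r", self.k2r)

    @property
    def dv(self) -> float:
        return self.k1r / self.k2r


def derive_constants(params: KineticParameters) -> DerivedConstants:
    """Compute KdVr, 1/KdVr, DV1 and BP from the five model constants."""
    kd_vr = params.koff / params.kon_vr
    return DerivedConstants(
        kd_vr=kd_vr,
        inv_kd_vr=1.0 / kd_vr,
        dv1=params.k1 / params.k2,
        bp=params.b_max / kd_vr,
    )


@dataclass
class TimeActivityCurve:
    """Framed, decay-corrected ROI concentrations.

    Frames are half-open intervals [start, start+duration) in minutes; the
    per-frame value is the time-average concentration over the frame in
    pmol/ml.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray
    conc: np.ndarray
    roi: str = "hippocampus"
    decay_corrected: bool = True
    n_clipped: int = 0  # frames floored at zero by the noise model

    def __post_init__(self) -> None:
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_duration = np.asarray(self.frame_duration, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        n = self.frame_start.size
        if not (self.frame_duration.size == n and self.conc.size == n):
            raise ValueError("frame_start, frame_duration and conc must have equal length")
        if np.any(self.frame_duration <= 0):
            raise ValueError("frame durations must be positive")
        if n > 1:
            ends = self.frame_start[:-1] + self.frame_duration[:-1]
            if np.any(np.diff(self.frame_start) <= 0) or np.any(ends > self.frame_start[1:] + 1e-12):
                raise ValueError("frames must be time-ordered and non-overlapping")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def end(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1])

    def __len__(self) -> int:
        return int(self.frame_start.size)

    def same_frames(self, other: "TimeActivityCurve", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.frame_start, other.frame_start, atol=tol)
            and np.allclose(self.frame_duration, other.frame_duration, atol=tol)
        )


class _PiecewiseDense:
    """Concatenation of per-segment dense ODE solutions."""

    def __init__(self, segments: list) -> None:
        self._segments = segments  # list of (t0, t1, OdeSolution)
        self.t_min = segments[0][0]
        self.t_max = segments[-1][1]

    def __call__(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < self.t_min - 1e-9) or np.any(t > self.t_max + 1e-9):
            raise ValueError("time outside simulated range")
        out = None
        for t0, t1, sol in self._segments:
            mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
            if not mask.any():
                continue
            vals = np.atleast_2d(sol(np.clip(t[mask], t0, t1)))
            if out is None:
                out = np.empty((vals.shape[0], t.size))
            out[:, mask] = vals
        return out


def _segment_times(t0: float, t1: float, breakpoints: Sequence[float]) -> list:
    pts = sorted({t0, t1, *(b for b in breakpoints if t0 < b < t1)})
    return list(zip(pts[:-1], pts[1:]))


def _integrate(rhs: Callable, t0: float, t1: float, y0: np.ndarray,
               breakpoints: Sequence[float], rtol: float, atol: float) -> _PiecewiseDense:
    segments = []
    y = np.asarray(y0, dtype=float)
    for a, b in _segment_times(t0, t1, breakpoints):
        res = solve_ivp(rhs, (a, b), y, method="LSODA", dense_output=True,
                        rtol=rtol, atol=atol)
        if not res.success:
            raise SimulationError(f"ODE solver failed on [{a}, {b}]: {res.message}")
        segments.append((a, b, res.sol))
        y = res.y[:, -1]
    return _PiecewiseDense(segments)


@dataclass
class SimulationResult:
    """Continuous-state solution of the 2TC target-region model.

    States are evaluated on ``t``; a dense interpolant is kept internally so
    that frame averaging can integrate the continuous curves.
    """

    t: np.ndarray
    hot_free: np.ndarray
    hot_bound: np.ndarray
    cold_free: np.ndarray
    cold_bound: np.ndarray
    params: KineticParameters
    _dense: _PiecewiseDense = field(repr=False, default=None)

    @property
    def total_hot(self) -> np.ndarray:
        return self.hot_free + self.hot_bound

    @property
    def total_ligand(self) -> np.ndarray:
        return self.hot_free + self.hot_bound + self.cold_free + self.cold_bound

    @property
    def free(self) -> np.ndarray:
        """Total free ligand (hot + cold), pmol/ml."""
        return self.hot_free + self.cold_free

    @property
    def bound(self) -> np.ndarray:
        """Total receptor-bound ligand (hot + cold), pmol/ml."""
        return self.hot_bound + self.cold_bound

    @property
    def occupancy(self) -> np.ndarray:
        return self.bound / self.params.b_max

    _SIGNALS = {
        "hot_free": (0,), "hot_bound": (1,), "cold_free": (2,), "cold_bound": (3,),
        "total_hot": (0, 1), "free": (0, 2), "bound": (1, 3), "total": (0, 1, 2, 3),
    }

    def signal(self, t, which: str = "total_hot") -> np.ndarray:
        """Evaluate a continuous signal (sum of states) at arbitrary times."""
        try:
            idx = self._SIGNALS[which]
        except KeyError:
            raise ValueError(f"unknown signal {which!r}") from None
        y = self._dense(t)
        return y[list(idx), :].sum(axis=0)


@dataclass
class ReferenceSimulation:
    """Continuous solution of the 1TC reference-region model."""

    t: np.ndarray
    conc: np.ndarray
    params: ReferenceParameters
    _dense: _PiecewiseDense = field(repr=False, default=None)

    def signal(self, t, which: str = "total") -> np.ndarray:
        return self._dense(t)[0, :]


_NEG_TOL_FRAC = 1e-9  # tolerated negative excursion, as a fraction of b_max


def simulate_target_tac(params: KineticParameters, plasma, grid,
                        rtol: float = DEFAULT_RTOL,
                        atol: float = DEFAULT_ATOL) -> SimulationResult:
    """Solve the hot+cold saturable 2TC model on a strictly increasing grid.

    ``plasma`` must expose ``hot(t)``, ``cold(t)`` (pmol/ml) and a
    ``breakpoints`` sequence of input-kink times used to split the
    integration so the stiff solver never steps across a discontinuity.
    The initial state is all-zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with at least two points")
    b_max, k1, k2, kon, koff = (params.b_max, params.k1, params.k2,
                                params.kon_vr, params.koff)

    def rhs(t, y):
        fh, bh, fc, bc = np.maximum(y, 0.0)  # clip before the bimolecular term
        avail = b_max - bh - bc
        on_h = kon * fh * avail
        on_c = kon * fc * avail
        return (
            k1 * plasma.hot(t) - k2 * fh - on_h + koff * bh,
            on_h - koff * bh,
            k1 * plasma.cold(t) - k2 * fc - on_c + koff * bc,
            on_c - koff * bc,
        )

    dense = _integrate(rhs, grid[0], grid[-1], np.zeros(4),
                       getattr(plasma, "breakpoints", ()), rtol, atol)
    y = dense(grid)
    if y.min() < -_NEG_TOL_FRAC * b_max:
        raise SimulationError(f"negative state beyond tolerance: min={y.min():.3e}")
    y = np.clip(y, 0.0, None)
    return SimulationResult(t=grid, hot_free=y[0], hot_bound=y[1],
                            cold_free=y[2], cold_bound=y[3],
                            params=params, _dense=dense)


def simulate_reference_tac(ref: ReferenceParameters, plasma, grid,
                           rtol: float = DEFAULT_RTOL,
                           atol: float = DEFAULT_ATOL) -> ReferenceSimulation:
    """Solve the 1TC reference model dC/dt = k1r·Cp*(t) − k2r·C."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with at least two points")

    def rhs(t, y):
        return (ref.k1r * plasma.hot(t) - ref.k2r * y[0],)

    dense = _integrate(rhs, grid[0], grid[-1], np.zeros(1),
                       getattr(plasma, "breakpoints", ()), rtol, atol)
    conc = dense(grid)[0]
    if conc.min() < -1e-9 * max(conc.max(), 1.0):
        raise SimulationError(f"negative state beyond tolerance: min={conc.min():.3e}")
    return ReferenceSimulation(t=grid, conc=np.clip(conc, 0.0, None),
                               params=ref, _dense=dense)


#: samples per frame for composite-Simpson frame averaging (odd)
_FRAME_QUAD_POINTS = 33


def frame_average(sim, frames, signal: str = "total_hot",
                  roi: str = "hippocampus") -> TimeActivityCurve:
    """Average a continuous simulated curve over PET frames.

    ``frames`` is a pair of arrays (start, duration) in minutes or an existing
    :class:`TimeActivityCurve` whose frame structure is reused.  Each frame
    value is the time-average of the continuous signal over
    [start, start+duration], computed by composite Simpson quadrature on the
    dense ODE interpolant.
    """
    if isinstance(frames, TimeActivityCurve):
        start, dur = frames.frame_start, frames.frame_duration
    else:
        start, dur = (np.asarray(a, dtype=float) for a in frames)
    dense = sim._dense
    if np.any(start < dense.t_min - 1e-9) or np.any(start + dur > dense.t_max + 1e-9):
        raise ValueError("frames fall outside the simulated grid")
    from scipy.integrate import simpson

    vals = np.empty(start.size)
    for i, (s, d) in enumerate(zip(start, dur)):
        ts = np.linspace(s, min(s + d, dense.t_max), _FRAME_QUAD_POINTS)
        ys = sim.signal(ts) if isinstance(sim, ReferenceSimulation) else sim.signal(ts, signal)
        vals[i] = simpson(ys, x=ts) / (ts[-1] - ts[0])
    return TimeActivityCurve(frame_start=start, frame_duration=dur,
                             conc=np.clip(vals, 0.0, None), roi=roi)


def occupancy_curve(sim: SimulationResult) -> np.ndarray:
    """Fractional receptor occupancy (B* + B)/Bmax on the simulation grid."""
    occ = sim.occupancy
    return np.clip(occ, 0.0, 1.0)
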