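"""Plasma input functions: hot and cold ligand concentration vs time.

Two concrete forms share one interface (``hot(t)``, ``cold(t)``,
``breakpoints``): an analytic bolus shape used by the synthetic-data
generator, and a sampled, linearly interpolated function assembled from
arterial blood measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnalyticPlasmaInput", "SampledPlasmaInput"]


class AnalyticPlasmaInput:
    """Superposition of mass-scaled single-injection bolus shapes.

    Each injection contributes ``mass * shape(t - t_inj)`` where ``shape``
    is the unit (1 nmol) bolus response: zero until ``delay``, a linear
    upslope of length ``rise`` to the peak, then a tri-exponential washout.
    Hot and cold ligand use the same shape scaled by their injected masses
    (superposition is exact, so an n-injection input is the sum of its
    single-injection inputs).
    """

    def __init__(self, events, amplitudes, rates, delay: float, rise: float,
                 scale: float) -> None:
        """``events``: iterable of (time_min, hot_mass_nmol, cold_mass_nmol).

        ``amplitudes`` are washout fractions (must sum to 1), ``rates`` the
        corresponding decay constants (/min, strictly decreasing), ``scale``
        the peak plasma concentration per injected nmol ((pmol/ml)/nmol).
        """
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.amplitudes.size != self.rates.size:
            raise ValueError("amplitudes and rates must have equal length")
        if np.any(self.amplitudes < 0) or not np.isclose(self.amplitudes.sum(), 1.0):
            raise ValueError("amplitudes must be non-negative fractions summing to 1")
        if np.any(self.rates <= 0) or np.any(np.diff(self.rates) >= 0):
            raise ValueError("rates must be positive and strictly decreasing")
        if delay < 0 or rise <= 0 or scale <= 0:
            raise ValueError("delay must be >= 0; rise and scale > 0")
        self.delay = float(delay)
        self.rise = float(rise)
        self.scale = float(scale)
        self.events = [(float(t), float(h), float(c)) for t, h, c in events]
        bps: list[float] = []
        for t, _, _ in self.events:
            bps += [t, t + self.delay, t + self.delay + self.rise]
        self.breakpoints = tuple(sorted(set(bps)))

    def unit_shape(self, tau):
        """Plasma concentration per injected nmol at time tau after injection."""
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        out = np.zeros_like(tau)
        up = (tau >= self.delay) & (tau < self.delay + self.rise)
        out[up] = self.scale * (tau[up] - self.delay) / self.rise
        down = tau >= self.delay + self.rise
        if down.any():
            s = tau[down] - self.delay - self.rise
            out[down] = self.scale * (
                self.amplitudes[None, :] * np.exp(-np.outer(s, self.rates))
            ).sum(axis=1)
        return out

    def _species(self, t, idx: int):
        scalar = np.isscalar(t) or np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t, dtype=float)
        for ev in self.events:
            mass = ev[idx]
            if mass > 0:
                out += mass * self.unit_shape(t - ev[0])
        return float(out[0]) if scalar else out

    def hot(self, t):
        return self._species(t, 1)

    def cold(self, t):
        return self._species(t, 2)


@dataclass
class SampledPlasmaInput:
    """Measured input function: linear interpolation between samples.

    Values are held at the last sample after it ends and at the first sample
    before it begins.  ``breakpoints`` should list injection times so that
    ODE integration restarts at each bolus.
    """

    times: np.ndarray
    hot_conc: np.ndarray
    cold_conc: np.ndarray | None = None
    breakpoints: tuple = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hot_conc = np.asarray(self.hot_conc, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.hot_conc.shape != self.times.shape:
            raise ValueError("hot_conc must match times")
        if self.cold_conc is not None:
            self.cold_conc = np.asarray(self.cold_conc, dtype=float)
            if self.cold_conc.shape != self.times.shape:
                raise ValueError("cold_conc must match times")

    def hot(self, t):
        return np.interp(np.asarray(t, dtype=float), self.times, self.hot_conc)

    def cold(self, t):
        t = np.asarray(t, dtype=float)
        if self.cold_conc is None:
            return np.zeros_like(t)
        return np.interp(t, self.times, self.cold_conc)
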