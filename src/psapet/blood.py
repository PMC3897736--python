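"""Arterial blood-sample processing.

Samples (50 µl nominal) are drawn into pre-weighed tubes containing 50 µl of
NaF (an esterase inhibitor stopping further ligand metabolism), gamma-counted,
background-subtracted and decay-corrected to the start of their injection
phase.  Mass-spectrometry concentrations are renormalised for the actual
blood volume drawn.  The corrected per-phase series concatenate into a
sampled plasma input function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plasma import SampledPlasmaInput

__all__ = [
    "BloodSample",
    "F18_HALF_LIFE_MIN",
    "correct_decay",
    "correct_dilution",
    "build_input_function",
]

#: physical half-life of fluorine-18, minutes
F18_HALF_LIFE_MIN = 109.77

#: nominal drawn blood volume and added NaF volume, ml
NOMINAL_BLOOD_ML = 0.05
NAF_ML = 0.05


@dataclass(frozen=True)
class BloodSample:
    """One arterial draw.  ``draw_time`` is minutes relative to the start of
    its injection phase (1–3); ``actual_volume`` comes from tube weighing and
    may differ from the nominal 0.05 ml."""

    draw_time: float
    counts: float            # CPM
    background: float        # CPM
    actual_volume: float = NOMINAL_BLOOD_ML   # ml
    naf_volume: float = NAF_ML                # ml
    phase: int = 1

    def __post_init__(self) -> None:
        if self.actual_volume <= 0 or self.naf_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.counts < 0 or self.background < 0:
            raise ValueError("counts must be non-negative")
        if self.draw_time < 0:
            raise ValueError("draw time must be non-negative")


def correct_decay(sample: BloodSample,
                  half_life: float = F18_HALF_LIFE_MIN) -> float:
    """Background-subtracted counts decay-corrected to the injection start.

    Returns (counts − background) · 2^(draw_time/half_life).  A negative net
    count (background above measured activity) is returned as-is so callers
    can flag and exclude it; it is not clamped.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    net = sample.counts - sample.background
    return net * 2.0 ** (sample.draw_time / half_life)


def correct_dilution(conc: float, actual_volume: float,
                     naf_volume: float = NAF_ML,
                     nominal_volume: float = NOMINAL_BLOOD_ML) -> float:
    """Renormalise a measured concentration to the nominal blood:NaF mix.

    The measured concentration reflects the actual dilution
    V/(V + V_NaF); the correction divides that out and applies the nominal
    0.05/(0.05+0.05) dilution instead:

        corrected = conc ÷ [V/(V + V_NaF)] × [V_nom/(V_nom + V_NaF)]

    At the nominal volume the correction is exactly the identity, and it is
    linear in ``conc``.
    """
    if actual_volume <= 0:
        raise ValueError("actual_volume must be positive")
    actual_dilution = actual_volume / (actual_volume + naf_volume)
    nominal_dilution = nominal_volume / (nominal_volume + naf_volume)
    return conc / actual_dilution * nominal_dilution


def build_input_function(samples, calibration: float,
                         phase_times=(0.0, 42.0, 70.0),
                         half_life: float = F18_HALF_LIFE_MIN) -> SampledPlasmaInput:
    """Assemble a sampled plasma input function from corrected blood draws.

    Per phase: background-subtract, decay-correct to the phase start, convert
    CPM to pmol/ml through ``calibration``, and place on the global clock at
    phase_time + draw_time.  Negative-net samples are excluded (their count
    is recorded on the returned object); each phase must retain at least two
    usable samples.  Between samples the function interpolates linearly and
    it is held at the last value after the final sample.
    """
    if calibration <= 0:
        raise ValueError("calibration must be positive")
    times, concs = [], []
    n_excluded = 0
    by_phase: dict[int, list[BloodSample]] = {}
    for s in samples:
        by_phase.setdefault(s.phase, []).append(s)
    for phase, group in sorted(by_phase.items()):
        if phase < 1 or phase > len(phase_times):
            raise ValueError(f"sample phase {phase} has no injection time")
        t0 = phase_times[phase - 1]
        usable = 0
        for s in sorted(group, key=lambda s: s.draw_time):
            net = correct_decay(s, half_life)
            if net < 0:
                n_excluded += 1
                continue
            times.append(t0 + s.draw_time)
            concs.append(net * calibration)
            usable += 1
        if usable < 2:
            raise ValueError(f"phase {phase}: fewer than 2 usable samples")
    order = np.argsort(times)
    times = np.asarray(times)[order]
    concs = np.asarray(concs)[order]
    if np.any(np.diff(times) <= 0):
        raise ValueError("duplicate sample times across phases")
    out = SampledPlasmaInput(times=times, hot_conc=concs,
                             breakpoints=tuple(phase_times))
    out.n_excluded = n_excluded
    return out
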