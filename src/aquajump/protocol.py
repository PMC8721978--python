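"""Heart-rate-reserve intensity protocol for water jumping sessions.

Exercise intensity is prescribed with the Karvonen method on a
water-adjusted maximal heart rate: the age-predicted maximum
(206.9 - 0.67*age) is lowered by the immersion bradycardia
``dHR = RHR_land - RHR_water``, and phase targets are fractions of the
water heart-rate reserve above the resting rate in water.  Jump cadence
ramps from a starting tempo in fixed increments until the target heart
rate is reached, after which a fixed number of terminal jumps is
performed at that intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhaseSpec",
    "IntensityTargets",
    "default_protocol",
    "predicted_mhr",
    "water_adjusted_mhr",
    "karvonen_target",
    "compute_targets",
    "resting_hr",
    "label_intensity",
]


@dataclass(frozen=True)
class PhaseSpec:
    """One intensity phase of the jumping protocol.

    Parameters
    ----------
    fraction : float
        Heart-rate-reserve fraction defining the phase target (0-1].
    label : str
        Intensity label attached to terminal jumps, e.g. ``"80"``.
    start_cadence : float or None
        Jump cadence (jumps/min) at phase start.  ``None`` means the
        phase resumes at the cadence reached at the end of the previous
        phase.
    increment : float
        Cadence increase (jumps/min) applied every ``step_s`` seconds.
    step_s : float
        Duration of each cadence step in seconds.
    terminal_jumps : int
        Number of jumps performed once the target heart rate is reached.
    """

    fraction: float
    label: str
    start_cadence: float | None = None
    increment: float = 5.0
    step_s: float = 20.0
    terminal_jumps: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.start_cadence is not None and self.start_cadence <= 0:
            raise ValueError("start_cadence must be positive")
        if self.increment < 0 or self.step_s <= 0:
            raise ValueError("cadence increments must be nonnegative, step_s positive")
        if self.terminal_jumps < 1:
            raise ValueError("terminal_jumps must be >= 1")


def default_protocol() -> list[PhaseSpec]:
    """The three-phase 50/65/80% HRR schedule starting at 80 jumps/min."""
    return [
        PhaseSpec(0.50, "50", start_cadence=80.0),
        PhaseSpec(0.65, "65"),
        PhaseSpec(0.80, "80"),
    ]


@dataclass(frozen=True)
class IntensityTargets:
    """Water-adjusted maximal heart rate and per-fraction HRR targets."""

    mhr_predicted: float
    delta_hr: float
    mhr_water: float
    target_hr: dict[float, float] = field(default_factory=dict)

    def target_for(self, fraction: float) -> float:
        return self.target_hr[fraction]


def predicted_mhr(age: float) -> float:
    """Age-predicted maximal heart rate, ``206.9 - 0.67*age`` (bpm)."""
    if age < 0:
        raise ValueError("age must be nonnegative")
    return 206.9 - 0.67 * age


def water_adjusted_mhr(mhr_predicted: float, rhr_land: float, rhr_water: float) -> float:
    """Immersion-adjusted maximum: MHR_water = MHR_predicted - (RHR_land - RHR_water)."""
    if min(mhr_predicted, rhr_land, rhr_water) <= 0:
        raise ValueError("heart rates must be positive")
    return mhr_predicted - (rhr_land - rhr_water)


def karvonen_target(mhr_water: float, rhr_water: float, fraction: float) -> float:
    """Karvonen target heart rate: ``(MHR_water - RHR_water)*fraction + RHR_water``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if mhr_water <= rhr_water:
        raise ValueError("mhr_water must exceed rhr_water")
    return (mhr_water - rhr_water) * fraction + rhr_water


def compute_targets(subject, fractions: Sequence[float] = (0.50, 0.65, 0.80)) -> IntensityTargets:
    """Full intensity prescription for a subject profile.

    ``subject`` needs ``age``, ``rhr_land`` and ``rhr_water`` attributes.
    """
    mhr_p = predicted_mhr(subject.age)
    mhr_w = water_adjusted_mhr(mhr_p, subject.rhr_land, subject.rhr_water)
    targets = {f: karvonen_target(mhr_w, subject.rhr_water, f) for f in fractions}
    return IntensityTargets(
        mhr_predicted=mhr_p,
        delta_hr=subject.rhr_land - subject.rhr_water,
        mhr_water=mhr_w,
        target_hr=targets,
    )


def resting_hr(hr_trace: np.ndarray, stand_duration: float = 300.0, window_s: float = 60.0) -> float:
    """Resting heart rate: mean of the final minute of a quiet-standing trace.

    ``hr_trace`` is sampled at 1 Hz; the standing window is its last
    ``stand_duration`` seconds and the resting rate averages the final
    ``window_s`` samples of that window.
    """
    hr = np.asarray(hr_trace, dtype=float)
    if hr.ndim != 1:
        raise ValueError("hr_trace must be 1-D")
    if hr.size < stand_duration:
        raise ValueError(
            f"trace of {hr.size} samples is shorter than the {stand_duration:.0f} s standing period"
        )
    n = int(round(window_s))
    return float(np.mean(hr[-n:]))


def label_intensity(
    landing_times_s: Sequence[float],
    hr_trace: np.ndarray,
    targets: IntensityTargets,
    phases: Sequence[PhaseSpec],
    phase_windows: Sequence[tuple[float, float]],
    fs_hr: float = 1.0,
) -> list[str]:
    """Assign an intensity label to each jump landing.

    Within each phase window the first heart-rate sample at or above the
    phase target opens a terminal window; the first ``terminal_jumps``
    landings from the start of that sample's interval onward receive the
    phase label.  Because the heart rate is sampled at ``fs_hr``, the
    true crossing is only localised to the sampling interval *ending* at
    the first supra-threshold sample, so candidate landings start at
    ``t_cross - 1/fs_hr``.  All other landings are labelled ``"ramp"``.
    A phase whose target is never reached contributes no labels and
    raises a ``UserWarning``.
    """
    times = np.asarray(landing_times_s, dtype=float)
    hr = np.asarray(hr_trace, dtype=float)
    if len(phases) != len(phase_windows):
        raise ValueError("phases and phase_windows must align")
    labels = ["ramp"] * times.size
    t_hr = np.arange(hr.size) / fs_hr
    for phase, (t0, t1) in zip(phases, phase_windows):
        target = targets.target_for(phase.fraction)
        in_win = (t_hr >= t0) & (t_hr < t1)
        reached = np.flatnonzero(in_win & (hr >= target))
        if reached.size == 0:
            warnings.warn(
                f"phase {phase.label}: target {target:.1f} bpm never reached; no jumps labelled",
                UserWarning,
                stacklevel=2,
            )
            continue
        t_cross = t_hr[reached[0]]
        candidates = np.flatnonzero((times >= t_cross - 1.0 / fs_hr) & (times < t1))
        for j in candidates[: phase.terminal_jumps]:
            labels[j] = phase.label
    return labels
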