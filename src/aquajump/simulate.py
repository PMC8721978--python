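"""Synthetic head-out water countermovement-jump sessions with known truth.

No public recordings exist for force-plate-instrumented jumping in
water, so every downstream stage is exercised on simulated sessions
whose ground truth is known by construction.  The generator emulates:

* a cohort of young women (age 23.6 +/- 1.83 y, height 158.2 +/- 5.33 cm,
  mass 53.1 +/- 7.50 kg) standing in 1 m of water;
* 1000 Hz vertical force traces built from a piecewise-smooth jump
  template (quiet stance at the buoyancy-reduced apparent weight,
  countermovement dip, push-off, flight near zero force, half-sine
  landing impulse) whose landing peaks follow per-intensity normal
  distributions (means 0.64 / 0.67 / 0.73 BW at 50 / 65 / 80% HRR);
* triaxial accelerometers at C7, L5 and TA whose per-jump peak
  resultant is linearly linked to the landing peak force,
  ``a = alpha0 + alpha1 * grf + N(0, sigma_a)``, with position-specific
  link parameters solved from the per-intensity acceleration means;
* a 1 Hz heart-rate trace relaxing first-order toward each Karvonen
  phase target, driving the cadence ramp (start 80 jumps/min,
  +5 every 20 s) and the five terminal jumps per phase.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import PhaseSpec, IntensityTargets, compute_targets, default_protocol, label_intensity
from .signal import G0

__all__ = [
    "ConfigurationError",
    "TemplateError",
    "SubjectProfile",
    "CohortParams",
    "AccLink",
    "SimulationConfig",
    "SessionTraces",
    "generate_subject",
    "synthesize_jump_waveform",
    "generate_session",
    "generate_cohort",
    "generate_regression_records",
]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


class TemplateError(ValueError):
    """Jump-template parameters that cannot produce a detectable landing."""


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and resting physiology of one participant.

    ``water_depth`` and ``height`` are in cm; PWDH (water depth as a
    percentage of body height) derives from them.  ``buoyancy_fraction``
    is the fraction of land body weight carried by buoyancy while
    standing, so the apparent weight in water is
    ``(1 - buoyancy_fraction)`` BW.
    """

    subject_id: str
    age: float
    height: float
    mass_land: float
    rhr_land: float
    rhr_water: float
    water_depth: float = 100.0
    buoyancy_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.age <= 0 or self.height <= 0 or self.mass_land <= 0:
            raise ValueError("age, height and mass must be positive")
        if not 0 < self.water_depth <= self.height:
            raise ValueError("water depth must be positive and no more than body height")
        for name in ("rhr_land", "rhr_water"):
            v = getattr(self, name)
            if not 20 < v < 220:
                raise ValueError(f"{name}={v} outside the physiologic range (20, 220) bpm")
        if not 0 <= self.buoyancy_fraction < 1:
            raise ValueError("buoyancy_fraction must be in [0, 1)")

    @property
    def pwdh(self) -> float:
        """Water depth as percent of body height."""
        return self.water_depth / self.height * 100.0

    @property
    def apparent_weight_bw(self) -> float:
        """Quiet-standing weight in water, in land body-weight units."""
        return 1.0 - self.buoyancy_fraction

    @property
    def water_weight_n(self) -> float:
        """Quiet-standing vertical force in water, Newtons."""
        return self.apparent_weight_bw * self.mass_land * G0


@dataclass(frozen=True)
class CohortParams:
    """(mean, sd) pairs and clamps for drawing subject profiles.

    Defaults reproduce the study cohort's anthropometrics; resting heart
    rates on land and the immersion drop are generic young-adult values
    since the study reports none.  Zero spreads are allowed (degenerate
    draws at the mean); negative spreads are a configuration error.
    """

    age: tuple[float, float] = (23.6, 1.83)
    height: tuple[float, float] = (158.2, 5.33)
    mass: tuple[float, float] = (53.1, 7.50)
    rhr_land: tuple[float, float] = (70.0, 6.0)
    delta_hr: tuple[float, float] = (8.0, 3.0)
    age_clamp: tuple[float, float] = (18.0, 45.0)
    height_clamp: tuple[float, float] = (140.0, 185.0)
    mass_clamp: tuple[float, float] = (35.0, 90.0)
    rhr_clamp: tuple[float, float] = (40.0, 110.0)

    def __post_init__(self) -> None:
        for name in ("age", "height", "mass", "rhr_land", "delta_hr"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{name} spread must be nonnegative, got {sd}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Redraw until inside the clamp; falls back to clipping after 1000 tries."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_subject(
    seed,
    cohort_params: CohortParams | None = None,
    subject_id: str = "S00",
    water_depth: float = 100.0,
    buoyancy_fraction: float = 0.55,
) -> SubjectProfile:
    """Draw one subject profile from the cohort distributions.

    Deterministic for a fixed integer seed; ``seed`` may also be a
    ``numpy.random.Generator`` to embed the draw in a larger stream.
    """
    p = cohort_params or CohortParams()
    rng = _as_rng(seed)
    age = _truncated_normal(rng, *p.age, *p.age_clamp)
    height = _truncated_normal(rng, *p.height, *p.height_clamp)
    mass = _truncated_normal(rng, *p.mass, *p.mass_clamp)
    rhr_land = _truncated_normal(rng, *p.rhr_land, *p.rhr_clamp)
    delta = rng.normal(*p.delta_hr) if p.delta_hr[1] > 0 else p.delta_hr[0]
    rhr_water = float(np.clip(rhr_land - delta, 35.0, p.rhr_clamp[1]))
    return SubjectProfile(
        subject_id=subject_id,
        age=age,
        height=height,
        mass_land=mass,
        rhr_land=rhr_land,
        rhr_water=rhr_water,
        water_depth=min(water_depth, height),
        buoyancy_fraction=buoyancy_fraction,
    )


@dataclass(frozen=True)
class AccLink:
    """Linear peak-acceleration / peak-force link for one wear-position.

    ``peak_acc = alpha0 + alpha1 * peak_grf + N(0, sigma)`` (g, BW).
    """

    alpha0: float
    alpha1: float
    sigma: float = 0.08

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("link sigma must be nonnegative")


def _default_acc_links() -> dict[str, AccLink]:
    # Intercept/slope solved from the per-intensity mean accelerations at
    # the 50% and 80% HRR mean peak forces (0.64 and 0.73 BW):
    # C7 1.51 -> 1.61 g, L5 1.47 -> 1.55 g, TA 1.55 -> 1.65 g.
    span = 0.73 - 0.64
    links = {}
    for pos, (a50, a80) in {"c7": (1.51, 1.61), "l5": (1.47, 1.55), "ta": (1.55, 1.65)}.items():
        slope = (a80 - a50) / span
        links[pos] = AccLink(alpha0=a50 - slope * 0.64, alpha1=slope)
    return links


@dataclass
class SimulationConfig:
    """All tunable knobs of the session generator.

    Per-intensity peak-force distributions and the acceleration links
    are keyed by phase label.  Heart-rate time constants are per phase;
    the relaxation asymptote sits ``hr_overshoot_bpm`` above the phase
    target so the target is crossed in finite time, and the constants
    are calibrated so default sessions yield roughly 34 / 45 / 53 jumps
    at the three intensities.
    """

    fs: float = 1000.0
    fs_hr: float = 1.0
    buoyancy_fraction: float = 0.55
    peak_grf_mean: dict[str, float] = field(default_factory=lambda: {"50": 0.64, "65": 0.67, "80": 0.73})
    peak_grf_sd: dict[str, float] = field(default_factory=lambda: {"50": 0.088, "65": 0.075, "80": 0.099})
    acc_link: dict[str, AccLink] = field(default_factory=_default_acc_links)
    subject_acc_offset_sd: float = 0.04
    landing_ms: float = 120.0
    flight_frac: float = 0.20
    dip_frac: float = 0.15
    push_frac: float = 0.15
    dip_depth: float = 0.5
    push_overshoot: float = 0.5
    force_noise_sd_bw: float = 0.005
    acc_noise_sd_g: float = 0.01
    hr_tau_s: dict[str, float] = field(default_factory=lambda: {"50": 8.4, "65": 16.0, "80": 16.4})
    hr_default_tau_s: float = 12.0
    hr_overshoot_bpm: float = 5.0
    hr_rest_tau_s: float = 30.0
    max_rest_s: float = 120.0
    lead_s: float = 5.0
    tail_s: float = 2.0
    off_axis_deg: float = 12.0
    max_ramp_s: float = 600.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.fs_hr <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if not 0 <= self.buoyancy_fraction < 1:
            raise ConfigurationError("buoyancy_fraction must be in [0, 1)")
        for d in (self.peak_grf_sd,):
            for k, v in d.items():
                if v < 0:
                    raise ConfigurationError(f"peak_grf_sd[{k}] must be nonnegative")
        labels = sorted(self.peak_grf_mean, key=float)
        means = [self.peak_grf_mean[k] for k in labels]
        if any(b < a for a, b in zip(means, means[1:])):
            raise ConfigurationError(
                f"per-intensity mean peak forces must be nondecreasing, got {dict(zip(labels, means))}"
            )
        if min(self.force_noise_sd_bw, self.acc_noise_sd_g, self.subject_acc_offset_sd) < 0:
            raise ConfigurationError("noise amplitudes must be nonnegative")


def noiseless(config: SimulationConfig | None = None) -> SimulationConfig:
    """Copy of a config with every stochastic amplitude set to zero."""
    cfg = config or SimulationConfig()
    links = {k: replace(v, sigma=0.0) for k, v in cfg.acc_link.items()}
    return replace(cfg, acc_link=links, force_noise_sd_bw=0.0, acc_noise_sd_g=0.0, subject_acc_offset_sd=0.0)


@dataclass
class SessionTraces:
    """Synchronised waveforms of one session plus simulator ground truth.

    ``force_v`` is in Newtons at ``fs``; ``acc`` maps wear-position to an
    ``(n, 3)`` array in g; ``hr`` is the 1 Hz heart-rate trace.  The
    ``ground_truth`` table carries, per jump: landing sample index, true
    landing peak force (BW), true peak resultant acceleration per
    position (g), cadence, phase and intensity label.
    """

    time: np.ndarray
    force_v: np.ndarray
    acc: dict[str, np.ndarray]
    hr: np.ndarray
    subject_id: str
    fs: float
    fs_hr: float
    ground_truth: pd.DataFrame
    phases: list[PhaseSpec] = field(default_factory=list)
    phase_windows: list[tuple[float, float]] = field(default_factory=list)
    targets: IntensityTargets | None = None

    def __post_init__(self) -> None:
        n = self.force_v.size
        if self.time.size != n:
            raise ValueError("time and force arrays must share length")
        for pos, a in self.acc.items():
            if a.shape != (n, 3):
                raise ValueError(f"acc[{pos!r}] must have shape ({n}, 3), got {a.shape}")
        if np.min(self.force_v) < 0:
            raise ValueError("vertical force must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.force_v.size


def synthesize_jump_waveform(
    peak_grf_bw: float,
    apparent_weight_bw: float,
    cadence: float,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """One jump period of vertical force in body-weight units.

    The period (``60 / cadence`` s) contains, in order: quiet stance at
    the apparent weight, a cosine countermovement dip, a push-off rise
    that returns to zero force at take-off, a zero-force flight, and a
    landing impulse rising from zero to ``peak_grf_bw`` and easing back
    to stance.  The sample nearest the impulse apex is set exactly to
    the requested peak so ground truth is exact at the sample grid.
    """
    cfg = config or SimulationConfig()
    if not 0 < apparent_weight_bw < 1:
        raise ValueError("apparent weight must be in (0, 1) BW")
    if not 60 <= cadence <= 200:
        raise ValueError(f"cadence must be within [60, 200] jumps/min, got {cadence}")
    if peak_grf_bw <= apparent_weight_bw:
        raise TemplateError(
            f"landing peak {peak_grf_bw:.3f} BW does not exceed the apparent weight "
            f"{apparent_weight_bw:.3f} BW; the landing would not register as the contact peak"
        )
    period = 60.0 / cadence
    n = int(round(cfg.fs * period))
    landing_n = int(round(min(cfg.landing_ms / 1000.0, 0.25 * period) * cfg.fs))
    flight_n = int(round(cfg.flight_frac * period * cfg.fs))
    dip_n = int(round(cfg.dip_frac * period * cfg.fs))
    push_n = int(round(cfg.push_frac * period * cfg.fs))
    stance_n = n - landing_n - flight_n - dip_n - push_n
    if stance_n <= 0:
        raise ConfigurationError("phase fractions leave no room for quiet stance")

    w = apparent_weight_bw
    dip_low = cfg.dip_depth * w
    # The push-off peak is capped just below the minimum landing peak the
    # session generator can draw (apparent weight + 0.05 BW) so that within
    # any landing contact — which runs through the next jump's push-off —
    # the maximum force is always the landing impulse.
    push_peak = w + min(cfg.push_overshoot * (peak_grf_bw - w), 0.04)

    stance = np.full(stance_n, w)
    u = np.arange(1, dip_n + 1) / dip_n
    dip = w - (w - dip_low) * 0.5 * (1 - np.cos(np.pi * u))
    u0 = math.asin(min(dip_low / push_peak, 1.0)) / math.pi
    u = np.arange(1, push_n + 1) / push_n
    push = push_peak * np.sin(np.pi * (u0 + (1 - u0) * u))
    flight = np.zeros(flight_n)
    rise_n = landing_n // 2
    fall_n = landing_n - rise_n
    u = np.arange(1, rise_n + 1) / rise_n
    rise = peak_grf_bw * np.sin(0.5 * np.pi * u)
    v = np.arange(1, fall_n + 1) / fall_n
    fall = w + (peak_grf_bw - w) * np.cos(0.5 * np.pi * v)
    segment = np.concatenate([stance, dip, push, flight, rise, fall])
    apex = stance_n + dip_n + push_n + flight_n + int(np.argmax(segment[-landing_n:]))
    segment[apex] = peak_grf_bw
    return np.maximum(segment, 0.0)


def _landing_layout(n: int, period: float, cfg: SimulationConfig) -> tuple[int, int]:
    """(landing start offset, landing length) of a period of n samples."""
    landing_n = int(round(min(cfg.landing_ms / 1000.0, 0.25 * period) * cfg.fs))
    return n - landing_n, landing_n


class _HRModel:
    """Piecewise first-order heart-rate relaxation with an exact clock."""

    def __init__(self, hr0: float):
        self.hr = hr0
        self.segments: list[tuple[float, float, float, float]] = []  # (t0, hr0, asym, tau)

    def start_segment(self, t: float, asym: float, tau: float) -> None:
        self.segments.append((t, self.hr, asym, tau))

    def advance(self, dt: float) -> float:
        t0, hr0, asym, tau = self.segments[-1]
        self.hr = asym + (self.hr - asym) * math.exp(-dt / tau) if math.isfinite(tau) else self.hr
        return self.hr

    def time_to_fall(self, level: float) -> float:
        """Time from *now* until the decaying segment falls to ``level`` (inf if never)."""
        _, _, asym, tau = self.segments[-1]
        if self.hr <= level:
            return 0.0
        if not math.isfinite(tau) or asym >= level:
            return math.inf
        return tau * math.log((self.hr - asym) / (level - asym))

    def sample(self, total_s: float, fs_hr: float) -> np.ndarray:
        t = np.arange(0.0, total_s, 1.0 / fs_hr)
        starts = np.array([s[0] for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(self.segments) - 1)
        out = np.empty_like(t)
        for i, (t0, hr0, asym, tau) in enumerate(self.segments):
            m = idx == i
            if not m.any():
                continue
            if math.isfinite(tau):
                out[m] = asym + (hr0 - asym) * np.exp(-(t[m] - t0) / tau)
            else:
                out[m] = hr0
        return out


def generate_session(
    subject: SubjectProfile,
    protocol: list[PhaseSpec] | None = None,
    config: SimulationConfig | None = None,
    seed=None,
) -> SessionTraces:
    """Simulate one continuous water-CMJ session for a subject.

    Jumps follow the cadence ramp until the phase's Karvonen target is
    reached (checked at each jump boundary against the analytic
    heart-rate curve), then the terminal jumps are performed at frozen
    cadence.  Between phases the heart rate recovers toward rest until
    it falls back to the first phase's target.  Intensity labels in the
    ground-truth table are assigned with :func:`~aquajump.protocol.label_intensity`
    on the generated heart-rate trace, so the generator and the protocol
    module share a single labelling rule.
    """
    cfg = config or SimulationConfig()
    phases = protocol if protocol is not None else default_protocol()
    if not phases:
        raise ConfigurationError("protocol must contain at least one phase")
    rng = _as_rng(seed if seed is not None else cfg.seed)

    targets = compute_targets(subject, fractions=[p.fraction for p in phases])
    w = subject.apparent_weight_bw
    fs = cfg.fs

    acc_offsets = {
        pos: (rng.normal(0.0, cfg.subject_acc_offset_sd) if cfg.subject_acc_offset_sd > 0 else 0.0)
        for pos in cfg.acc_link
    }

    chunks: list[np.ndarray] = [np.full(int(round(cfg.lead_s * fs)), w)]
    n_samples = chunks[0].size
    t = n_samples / fs

    hr = _HRModel(subject.rhr_water)
    hr.start_segment(0.0, subject.rhr_water, math.inf)

    rows: list[dict] = []
    phase_windows: list[tuple[float, float]] = []
    cadence = phases[0].start_cadence if phases[0].start_cadence is not None else 80.0

    for k, phase in enumerate(phases):
        if phase.label not in cfg.peak_grf_mean:
            raise ConfigurationError(f"no peak-force distribution configured for phase {phase.label!r}")
        target = targets.target_for(phase.fraction)
        tau = cfg.hr_tau_s.get(phase.label, cfg.hr_default_tau_s)
        hr.start_segment(t, target + cfg.hr_overshoot_bpm, tau)
        phase_t0 = t
        if phase.start_cadence is not None:
            cadence = phase.start_cadence
        mu, sd = cfg.peak_grf_mean[phase.label], cfg.peak_grf_sd[phase.label]
        terminal_left: int | None = None
        cad_now = cadence_terminal = cadence
        while True:
            if terminal_left is None and hr.hr >= target:
                terminal_left = phase.terminal_jumps
                cadence_terminal = cadence
            if terminal_left == 0:
                break
            if terminal_left is None and t - phase_t0 > cfg.max_ramp_s:
                warnings.warn(
                    f"phase {phase.label}: target {target:.1f} bpm not reached within "
                    f"{cfg.max_ramp_s:.0f} s; phase abandoned without terminal jumps",
                    UserWarning,
                    stacklevel=2,
                )
                break
            if terminal_left is None:
                steps = int((t - phase_t0) / phase.step_s)
                cad_now = min(cadence + phase.increment * steps, 200.0)
            else:
                cad_now = cadence_terminal
            peak = rng.normal(mu, sd) if sd > 0 else mu
            peak = max(peak, w + 0.05)
            seg = synthesize_jump_waveform(peak, w, cad_now, cfg)
            land_off, landing_n = _landing_layout(seg.size, 60.0 / cad_now, cfg)
            apex = land_off + int(np.argmax(seg[land_off:]))
            row = {
                "phase": phase.label,
                "is_terminal": terminal_left is not None,
                "start_idx": n_samples,
                "landing_idx": n_samples + apex,
                "landing_time_s": (n_samples + apex) / fs,
                "cadence": cad_now,
                "peak_grf_bw": peak,
                "landing_n": landing_n,
            }
            for pos, link in cfg.acc_link.items():
                a = link.alpha0 + link.alpha1 * peak + acc_offsets[pos]
                if link.sigma > 0:
                    a += rng.normal(0.0, link.sigma)
                    a = max(a, 1.2)
                row[f"peak_acc_{pos}"] = a
            rows.append(row)
            chunks.append(seg)
            n_samples += seg.size
            hr.advance(seg.size / fs)
            t = n_samples / fs
            if terminal_left is not None:
                terminal_left -= 1
        cadence = cadence_terminal if terminal_left is not None else cad_now
        phase_windows.append((phase_t0, t))

        if k < len(phases) - 1:
            recovery_level = targets.target_for(phases[0].fraction)
            hr.start_segment(t, subject.rhr_water, cfg.hr_rest_tau_s)
            rest_s = min(max(hr.time_to_fall(recovery_level), 5.0), cfg.max_rest_s)
            rest_n = int(round(rest_s * fs))
            chunks.append(np.full(rest_n, w))
            n_samples += rest_n
            hr.advance(rest_n / fs)
            t = n_samples / fs

    tail_n = int(round(cfg.tail_s * fs))
    chunks.append(np.full(tail_n, w))
    n_samples += tail_n
    hr.start_segment(t, subject.rhr_water, cfg.hr_rest_tau_s)
    total_s = n_samples / fs

    force_bw = np.concatenate(chunks)
    gt = pd.DataFrame(rows)
    gt.insert(0, "jump_index", np.arange(len(gt)))
    gt.insert(0, "subject_id", subject.subject_id)

    acc = _synthesize_acceleration(force_bw, gt, w, cfg, rng)

    if cfg.force_noise_sd_bw > 0:
        force_bw = force_bw + rng.normal(0.0, cfg.force_noise_sd_bw, force_bw.size)
    force_n = np.maximum(force_bw, 0.0) * subject.mass_land * G0

    hr_trace = hr.sample(total_s, cfg.fs_hr)

    labels = label_intensity(
        gt["landing_time_s"].to_numpy() if len(gt) else [],
        hr_trace,
        targets,
        phases,
        phase_windows,
        cfg.fs_hr,
    )
    gt["intensity"] = labels

    return SessionTraces(
        time=np.arange(n_samples) / fs,
        force_v=force_n,
        acc=acc,
        hr=hr_trace,
        subject_id=subject.subject_id,
        fs=fs,
        fs_hr=cfg.fs_hr,
        ground_truth=gt,
        phases=list(phases),
        phase_windows=phase_windows,
        targets=targets,
    )


def _synthesize_acceleration(
    force_bw: np.ndarray, gt: pd.DataFrame, w: float, cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Triaxial traces whose peak resultant per jump matches the drawn link values.

    A resultant profile is built per position (1 g grounded, ~0 g in
    flight, landing bump peaking at the drawn value, small push-off
    bump) and decomposed onto axes through a slowly wandering tilt, so
    the Euclidean norm reconstructs the profile exactly before noise.
    """
    n = force_bw.size
    grounded = force_bw > 0.05
    out: dict[str, np.ndarray] = {}
    t = np.arange(n) / cfg.fs
    theta = np.deg2rad(cfg.off_axis_deg) * (1.0 + 0.2 * np.sin(2 * np.pi * t / 7.0))
    phi = 2 * np.pi * t / 11.0
    for pos in cfg.acc_link:
        r = np.where(grounded, 1.0, 0.05)
        for row in gt.itertuples():
            a_peak = getattr(row, f"peak_acc_{pos}")
            landing_n = int(row.landing_n)
            apex = int(row.landing_idx)
            rise_n = landing_n // 2
            fall_n = landing_n - rise_n
            start = apex - rise_n + 1
            u = np.arange(1, rise_n + 1) / rise_n
            r[start : apex + 1] = 0.05 + (a_peak - 0.05) * np.sin(0.5 * np.pi * u)
            v = np.arange(1, fall_n + 1) / fall_n
            stop = min(apex + fall_n + 1, n)
            r[apex + 1 : stop] = (1.0 + (a_peak - 1.0) * np.cos(0.5 * np.pi * v))[: stop - apex - 1]
            r[apex] = a_peak
            # modest push-off bump just before take-off of the *next* cycle
            push_mid = int(row.start_idx) + int(0.5 * (apex - int(row.start_idx)))
            pn = max(landing_n // 2, 1)
            lo = max(push_mid - pn, 0)
            bump = 1.0 + 0.1 * (a_peak - 1.0) * np.sin(np.pi * np.arange(push_mid - lo) / pn)
            r[lo:push_mid] = np.maximum(r[lo:push_mid], bump)
        az = r * np.cos(theta)
        ax = r * np.sin(theta) * np.cos(phi)
        ay = r * np.sin(theta) * np.sin(phi)
        axes = np.column_stack([ax, ay, az])
        if cfg.acc_noise_sd_g > 0:
            axes = axes + rng.normal(0.0, cfg.acc_noise_sd_g, axes.shape)
        out[pos] = axes
    return out


def generate_cohort(
    n_subjects: int,
    config: SimulationConfig | None = None,
    seed=None,
    protocol: list[PhaseSpec] | None = None,
    cohort_params: CohortParams | None = None,
) -> tuple[list[SubjectProfile], list[SessionTraces], pd.DataFrame]:
    """Simulate a cohort of subjects; returns profiles, sessions and the pooled truth table."""
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be at least 1")
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(seed if seed is not None else cfg.seed)
    subjects: list[SubjectProfile] = []
    sessions: list[SessionTraces] = []
    tables: list[pd.DataFrame] = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subj = generate_subject(
            rng, cohort_params, subject_id=f"S{i:02d}", buoyancy_fraction=cfg.buoyancy_fraction
        )
        traces = generate_session(subj, protocol, cfg, seed=rng)
        subjects.append(subj)
        sessions.append(traces)
        tables.append(traces.ground_truth)
    truth = pd.concat(tables, ignore_index=True)
    return subjects, sessions, truth


def generate_regression_records(
    n_subjects: int = 12,
    jumps_per_subject: int = 132,
    seed=None,
    intercept: float | None = None,
    coefficients: dict[str, float] | None = None,
    noise_sd: float = 0.07,
    c7_mean: float = 1.565,
    c7_sd: float = 0.125,
    cohort_params: CohortParams | None = None,
) -> pd.DataFrame:
    """Per-jump records whose outcome follows a known linear model exactly.

    Subject covariates (PWDH, age, weight) are drawn from the cohort
    distributions; per-jump C7 peak acceleration is normal around the
    validation-set mean; ``grf_v_l_bw`` is the linear model's value plus
    ``N(0, noise_sd)``.  Used for parameter-recovery experiments where
    the truth must be the model itself rather than the waveform chain.
    """
    from .regression import REFERENCE_EQUATION

    if intercept is None:
        intercept = REFERENCE_EQUATION.intercept
    coeffs = coefficients or dict(REFERENCE_EQUATION.coefficients)
    rng = _as_rng(seed)
    frames = []
    for i in range(n_subjects):
        subj = generate_subject(rng, cohort_params, subject_id=f"S{i:02d}")
        c7 = rng.normal(c7_mean, c7_sd, jumps_per_subject)
        y = (
            intercept
            + coeffs.get("c7acc", 0.0) * c7
            + coeffs.get("pwdh", 0.0) * subj.pwdh
            + coeffs.get("age", 0.0) * subj.age
            + coeffs.get("weight", 0.0) * subj.mass_land
        )
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, jumps_per_subject)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subj.subject_id,
                    "c7acc": c7,
                    "pwdh": subj.pwdh,
                    "age": subj.age,
                    "weight": subj.mass_land,
                    "grf_v_l_bw": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
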