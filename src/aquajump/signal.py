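"""Waveform processing: filtering, jump segmentation and feature extraction.

The processing chain mirrors a standard force-plate/IMU workflow for
continuous jumping in water: every channel is low-pass filtered
(zero-phase Butterworth, 50 Hz cut-off by default), the three axes of
each accelerometer are combined into a resultant, quiet standing yields
the subject's *water body weight* (reduced below land weight by
buoyancy), and landing contacts are the supra-threshold runs of
vertical force exceeding 10% of that water body weight.  Per-jump
scalars are the peak force — normalised by land body weight to
``GRF_V_L_BW`` — and the peak resultant acceleration of each
wear-position inside the landing contact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "G0",
    "ContactEvent",
    "lowpass_filter",
    "resultant_acceleration",
    "water_body_weight",
    "segment_contacts",
    "normalize_grf",
    "extract_jump_features",
    "process_session",
]

#: Standard gravity used for body-weight <-> Newton conversion (m/s^2).
G0 = 9.80665


@dataclass
class ContactEvent:
    """One supra-threshold contact interval, ``[start_index, end_index)``.

    ``preceded_by_flight`` distinguishes jump landings from the initial
    stance: only contacts entered from a flight phase count as jumps.
    Peak fields are filled by :func:`extract_jump_features`.
    """

    start_index: int
    end_index: int
    preceded_by_flight: bool
    peak_force_index: int
    peak_grf_bw: float | None = None
    peak_acc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise ValueError("contact interval must satisfy 0 <= start < end")
        if not self.start_index <= self.peak_force_index < self.end_index:
            raise ValueError("peak_force_index must lie inside the contact interval")

    @property
    def duration(self) -> int:
        return self.end_index - self.start_index


def lowpass_filter(
    x: np.ndarray, fs: float, cutoff: float = 50.0, order: int = 6
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    A filter of the given order is applied forward and backward
    (``sosfiltfilt``), which cancels phase lag — important so filtered
    peaks keep their timing — at the price of squaring the magnitude
    response.  DC gain is exactly 1.

    Raises
    ------
    ValueError
        If ``cutoff`` is not below the Nyquist frequency or the signal
        is too short for the filter's padding.
    """
    x = np.asarray(x, dtype=float)
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2}); got {cutoff}")
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= padlen:
        raise ValueError(
            f"signal of {x.size} samples is too short for order-{order} zero-phase "
            f"filtering (needs > {padlen} samples of padding)"
        )
    return sps.sosfiltfilt(sos, x)


def resultant_acceleration(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm of the three accelerometer axes."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError(f"axis shapes differ: {ax.shape}, {ay.shape}, {az.shape}")
    return np.sqrt(ax**2 + ay**2 + az**2)


def water_body_weight(
    force_v: np.ndarray, quiet_window: tuple[int, int], fs: float = 1000.0
) -> float:
    """Water body weight: mean vertical force over a quiet-standing window (N).

    The window is a half-open sample interval and must span at least
    0.5 s.  A warning is raised when the window appears to contain a
    flight phase (samples far below the window's typical level), which
    would bias the mean low.
    """
    force_v = np.asarray(force_v, dtype=float)
    lo, hi = quiet_window
    if not 0 <= lo < hi <= force_v.size:
        raise ValueError("quiet_window must lie within the trace")
    if (hi - lo) < 0.5 * fs:
        raise ValueError("quiet-standing window must span at least 0.5 s")
    window = force_v[lo:hi]
    med = float(np.median(window))
    if med > 0 and np.min(window) < 0.5 * med:
        warnings.warn(
            "quiet-standing window contains samples below half its median force; "
            "it may overlap a flight phase",
            UserWarning,
            stacklevel=2,
        )
    return float(np.mean(window))


def segment_contacts(
    grf_v: np.ndarray,
    wbw: float,
    threshold_frac: float = 0.10,
    min_flight_ms: float = 80.0,
    min_contact_ms: float = 50.0,
    fs: float = 1000.0,
) -> list[ContactEvent]:
    """Find ground contacts as runs of force above a water-body-weight fraction.

    Samples with ``grf_v > threshold_frac * wbw`` form candidate
    contacts.  Sub-threshold gaps shorter than ``min_flight_ms`` are
    treated as chatter and merged; gaps at least that long are flight
    phases.  Contacts shorter than ``min_contact_ms`` are discarded.
    ``preceded_by_flight`` is True when a flight-length gap (or a
    sub-threshold lead-in of flight length at the trace start) precedes
    the contact, so the initial quiet stance is excluded from jump
    counting.
    """
    grf_v = np.asarray(grf_v, dtype=float)
    if wbw <= 0:
        raise ValueError("water body weight must be positive")
    if grf_v.ndim != 1:
        raise ValueError("expected a 1-D force trace")
    threshold = threshold_frac * wbw
    above = grf_v > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(grf_v.size)

    min_flight = int(round(min_flight_ms / 1000.0 * fs))
    min_contact = int(round(min_contact_ms / 1000.0 * fs))

    # Merge runs separated by sub-flight-length gaps (threshold chatter).
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_flight:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[ContactEvent] = []
    prev_end = 0
    for s, e in merged:
        gap = s - prev_end
        prev_end = e
        if e - s < min_contact:
            continue
        peak_idx = s + int(np.argmax(grf_v[s:e]))
        events.append(
            ContactEvent(
                start_index=s,
                end_index=e,
                preceded_by_flight=gap >= min_flight,
                peak_force_index=peak_idx,
            )
        )
    return events


def normalize_grf(force_v, mass_land: float):
    """Normalise force in Newtons by land body weight: ``F / (m * g0)`` (BW)."""
    if mass_land <= 0:
        raise ValueError("mass_land must be positive")
    return np.asarray(force_v, dtype=float) / (mass_land * G0)


def extract_jump_features(
    traces,
    events: list[ContactEvent],
    subject,
    intensity_labels=None,
    cadences=None,
    cutoff: float = 50.0,
    order: int = 6,
    filter_first: bool = True,
) -> pd.DataFrame:
    """Build the per-jump feature table from segmented contacts.

    For every landing (contact with ``preceded_by_flight``) the peak
    normalised vertical force (``grf_v_l_bw``, BW) and the peak filtered
    resultant acceleration of each wear-position (g) are taken inside
    the contact interval.  Each axis is filtered before the resultant is
    formed (``filter_first=True``); the reverse order is available as a
    flag since the two do not commute.  Subject-level covariates (PWDH,
    age, weight) are attached to every row.
    """
    if not events:
        raise ValueError("no contact events supplied")
    n = traces.force_v.size
    for ev in events:
        if ev.end_index > n:
            raise IndexError(f"contact event [{ev.start_index}, {ev.end_index}) exceeds trace length {n}")

    force_bw = normalize_grf(lowpass_filter(traces.force_v, traces.fs, cutoff, order), subject.mass_land)
    resultants: dict[str, np.ndarray] = {}
    for pos, axes in traces.acc.items():
        if filter_first:
            fx, fy, fz = (lowpass_filter(axes[:, i], traces.fs, cutoff, order) for i in range(3))
            resultants[pos] = resultant_acceleration(fx, fy, fz)
        else:
            res = resultant_acceleration(axes[:, 0], axes[:, 1], axes[:, 2])
            resultants[pos] = lowpass_filter(res, traces.fs, cutoff, order)

    landings = [ev for ev in events if ev.preceded_by_flight]
    if intensity_labels is not None and len(intensity_labels) != len(landings):
        raise ValueError("intensity_labels must align with landing events")
    if cadences is not None and len(cadences) != len(landings):
        raise ValueError("cadences must align with landing events")

    rows = []
    for j, ev in enumerate(landings):
        sl = slice(ev.start_index, ev.end_index)
        seg = force_bw[sl]
        ev.peak_force_index = ev.start_index + int(np.argmax(seg))
        ev.peak_grf_bw = float(np.max(seg))
        for pos, res in resultants.items():
            ev.peak_acc[pos] = float(np.max(res[sl]))
        rows.append(
            {
                "subject_id": subject.subject_id,
                "jump_index": j,
                "intensity": intensity_labels[j] if intensity_labels is not None else "ramp",
                "cadence": float(cadences[j]) if cadences is not None else np.nan,
                "grf_v_l_bw": ev.peak_grf_bw,
                "acc_c7": ev.peak_acc.get("c7", np.nan),
                "acc_l5": ev.peak_acc.get("l5", np.nan),
                "acc_ta": ev.peak_acc.get("ta", np.nan),
                "pwdh": subject.pwdh,
                "age": subject.age,
                "weight": subject.mass_land,
            }
        )
    return pd.DataFrame(rows)


def process_session(
    traces,
    subject,
    cutoff: float = 50.0,
    order: int = 6,
    threshold_frac: float = 0.10,
    min_flight_ms: float = 80.0,
    min_contact_ms: float = 50.0,
    quiet_window_s: tuple[float, float] = (0.5, 4.5),
) -> tuple[list[ContactEvent], pd.DataFrame]:
    """Full single-session chain: filter, weigh, segment, label, extract.

    Intensity labels are derived from the session's heart-rate trace and
    Karvonen targets when the traces carry protocol metadata
    (``targets``, ``phases``, ``phase_windows``); otherwise all jumps
    are labelled ``"ramp"``.  Cadences are taken from the simulator's
    ground truth when available and aligned in count.
    """
    from .protocol import label_intensity

    fs = traces.fs
    filtered = lowpass_filter(traces.force_v, fs, cutoff, order)
    qlo, qhi = (int(round(t * fs)) for t in quiet_window_s)
    wbw = water_body_weight(filtered, (qlo, qhi), fs)
    events = segment_contacts(filtered, wbw, threshold_frac, min_flight_ms, min_contact_ms, fs)
    landings = [ev for ev in events if ev.preceded_by_flight]

    labels = None
    if getattr(traces, "targets", None) is not None and getattr(traces, "phases", None):
        landing_times = [ev.peak_force_index / fs for ev in landings]
        labels = label_intensity(
            landing_times, traces.hr, traces.targets, traces.phases, traces.phase_windows, traces.fs_hr
        )

    cadences = None
    gt = getattr(traces, "ground_truth", None)
    if gt is not None and len(gt) == len(landings):
        cadences = gt["cadence"].to_numpy()

    features = extract_jump_features(
        traces, events, subject, intensity_labels=labels, cadences=cadences, cutoff=cutoff, order=order
    )
    return events, features
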