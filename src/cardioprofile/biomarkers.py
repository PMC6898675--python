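"""Action-potential biomarkers: APD90, APA, delta-APD%, EADs, alternans.

Detectors consume one :class:`~cardioprofile.engine.BeatTrace` (or bare
time/voltage arrays) on the uniform 0.1 ms grid.  Conventions:

* APD is measured from the time of maximum upstroke velocity, not stimulus
  onset; the repolarization level for APD_f is
  ``L = v_peak - f * (v_peak - v_rest)`` with ``v_rest`` the voltage at the
  sample immediately before stimulus onset, and the last downward crossing of
  L counts (so EAD-prolonged beats report their full duration).
* An early afterdepolarization (EAD) is a secondary depolarization between
  the primary peak and terminal repolarization: voltage passes a local
  minimum above ``v_gate`` and subsequently rises by at least ``theta_rise``
  mV.  Detection runs on a lightly smoothed copy of the trace (1 ms moving
  average) so sub-millivolt sampling noise cannot seed spurious extrema; it
  is invariant to time shifts and voltage offsets.
* AP alternans is a period-2 alternation of the APD90 series (mean
  beat-to-beat delta above ``theta_alt`` with consistent phase) or of the
  per-beat EAD count (e.g. 1-vs-2 EAD upstrokes on alternating beats).

Thresholds (theta_rise = 2 mV, v_gate = -40 mV, 10 ms post-peak blanking,
theta_alt = 5 ms over a 10-beat window) are package choices, configurable on
every call and echoed in profile outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "REPOL_FAILURE",
    "RepolarizationFailure",
    "BeatBiomarkers",
    "RateAdaptationCurve",
    "AlternansReport",
    "apd",
    "apa",
    "delta_apd_percent",
    "detect_eads",
    "detect_alternans",
    "ead_onset_cl",
    "notch_present",
    "beat_biomarkers",
]

THETA_RISE = 2.0       # mV, minimum EAD secondary rise
V_GATE = -40.0         # mV, EAD local minimum must sit above this
BLANK_MS = 10.0        # ms, post-peak blanking window
NOTCH_GUARD_MS = 60.0  # ms post-upstroke: phase-1 notch/dome exclusion
THETA_ALT = 5.0        # ms, APD alternans magnitude threshold
ALT_WINDOW = 10        # beats
UPSTROKE_DVDT = 10.0   # mV/ms, minimum upstroke velocity
SMOOTH_MS = 1.0        # ms, moving-average width for extrema detection


class RepolarizationFailure:
    """Sentinel: the beat never repolarized to the requested level."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "REPOL_FAILURE"

    def __bool__(self):
        return False


REPOL_FAILURE = RepolarizationFailure()


@dataclass
class BeatBiomarkers:
    """Per-beat biomarker bundle."""

    apd90: float | RepolarizationFailure
    apa: float
    v_rest: float
    v_peak: float
    ead_count: int
    ead_times: list[float]
    notch_present: bool


@dataclass
class RateAdaptationCurve:
    """CL -> (APD90, EAD flag, alternans flag) map for one drug x cell."""

    points: dict[float, tuple[float, bool, bool]] = field(default_factory=dict)

    def add(self, cl: float, apd90: float, ead_flag: bool,
            alternans_flag: bool) -> None:
        self.points[float(cl)] = (apd90, bool(ead_flag), bool(alternans_flag))

    def cls(self) -> list[float]:
        return sorted(self.points)

    def ead_flags(self) -> dict[float, bool]:
        return {cl: self.points[cl][1] for cl in self.cls()}


@dataclass
class AlternansReport:
    delta_apd: float              # ms, mean |APD(n) - APD(n-1)| over window
    is_alternans: bool
    pattern: str | None = None    # e.g. "APD alternation", "EAD-count alternation"
    valid: bool = True            # False when the window held repol failures


def _smooth(v: np.ndarray, dt: float, width_ms: float = SMOOTH_MS) -> np.ndarray:
    n = max(1, int(round(width_ms / dt)))
    if n <= 1:
        return v
    kernel = np.ones(n) / n
    pad = np.concatenate([np.full(n // 2, v[0]), v, np.full(n - 1 - n // 2, v[-1])])
    return np.convolve(pad, kernel, mode="valid")


def _upstroke_index(t: np.ndarray, v: np.ndarray) -> int:
    dvdt = np.diff(v) / np.diff(t)
    i = int(np.argmax(dvdt))
    if dvdt[i] <= UPSTROKE_DVDT:
        raise ValueError(
            f"trace has no upstroke (max dV/dt = {dvdt[i]:.2f} mV/ms)")
    return i


def apd_from_arrays(t: np.ndarray, v: np.ndarray, fraction: float = 0.9):
    """APD at the given repolarization fraction; array-level workhorse."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    iu = _upstroke_index(t, v)
    v_rest = v[0]
    seg = v[iu:]
    ipk = iu + int(np.argmax(seg))
    v_peak = v[ipk]
    level = v_peak - fraction * (v_peak - v_rest)
    # inclusive comparison so fraction = 1.0 (level = rest) still crosses
    below = v[ipk:] <= level
    if not below.any():
        return REPOL_FAILURE
    # last downward crossing of the level
    cross = np.nonzero(~below[:-1] & below[1:])[0]
    if cross.size == 0:
        # already below at peak+1 sample (degenerate); fall back to first below
        idx = ipk + int(np.argmax(below))
        return float(t[idx] - t[iu])
    j = ipk + cross[-1]
    # linear interpolation between samples j and j+1
    frac = (v[j] - level) / (v[j] - v[j + 1])
    t_cross = t[j] + frac * (t[j + 1] - t[j])
    return float(t_cross - t[iu])


def apd(trace, fraction: float = 0.9):
    """APD_f of one beat (ms), or REPOL_FAILURE if V never recrosses the level."""
    return apd_from_arrays(trace.t, trace.v, fraction)


def apa(trace) -> float:
    """Action-potential amplitude: v_peak - v_rest (mV)."""
    v = np.asarray(trace.v, dtype=float)
    iu = _upstroke_index(np.asarray(trace.t, dtype=float), v)
    return float(np.max(v[iu:]) - v[0])


def delta_apd_percent(apd_drug: float, apd_control: float) -> float:
    """100 * (APD_drug - APD_control) / APD_control; negative = shortening."""
    for name, val in (("apd_drug", apd_drug), ("apd_control", apd_control)):
        if isinstance(val, RepolarizationFailure):
            raise ValueError(f"{name} is a repolarization failure; "
                             "delta-APD%% undefined")
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"{name} must be finite and positive, got {val}")
    return 100.0 * (apd_drug - apd_control) / apd_control


def _local_extrema(v: np.ndarray):
    """Indices of local minima and maxima from sign changes of the slope."""
    d = np.diff(v)
    s = np.sign(d)
    # carry the previous nonzero sign across flat runs
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    sc = s[1:] * s[:-1]
    minima = np.nonzero((sc < 0) & (s[1:] > 0))[0] + 1
    maxima = np.nonzero((sc < 0) & (s[1:] < 0))[0] + 1
    return minima, maxima


def ead_count_from_arrays(t: np.ndarray, v: np.ndarray,
                          theta_rise: float = THETA_RISE,
                          v_gate: float = V_GATE,
                          blank_ms: float = BLANK_MS):
    count, _ = _detect_eads_arrays(t, v, theta_rise, v_gate, blank_ms)
    return count


def _detect_eads_arrays(t, v, theta_rise, v_gate, blank_ms,
                        notch_guard_ms=NOTCH_GUARD_MS):
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    dt = t[1] - t[0]
    try:
        iu = _upstroke_index(t, v)
    except ValueError:
        return 0, []
    vs = _smooth(v, dt)
    ipk = iu + int(np.argmax(vs[iu:]))
    # the phase-1 notch -> dome transition is not an EAD: skip the guard
    # window after the upstroke as well as the post-peak blanking window
    start = max(ipk + max(1, int(round(blank_ms / dt))),
                iu + int(round(notch_guard_ms / dt)))
    if start >= vs.size - 2:
        return 0, []
    seg = vs[start:]
    minima, _ = _local_extrema(seg)
    times: list[float] = []
    next_free = 0
    for im in minima:
        if im < next_free:
            continue
        v_min = seg[im]
        if v_min <= v_gate:
            continue
        # prominence of the rise: highest point reached before the voltage
        # drops back below this minimum (robust to sampling noise)
        below = np.nonzero(seg[im + 1:] < v_min)[0]
        j = im + 1 + below[0] if below.size else seg.size
        span = seg[im:j]
        rise = float(span.max() - v_min)
        if rise >= theta_rise:
            times.append(float(t[start + im]))
            next_free = im + int(span.argmax())  # one count per upstroke
    return len(times), times


def detect_eads(trace, theta_rise: float = THETA_RISE, v_gate: float = V_GATE,
                blank_ms: float = BLANK_MS) -> tuple[int, list[float]]:
    """Count secondary depolarizations on one beat.

    Returns ``(ead_count, ead_times)`` where each time marks the local
    voltage minimum from which the secondary upstroke departs.  Clean
    monotone-repolarizing beats return ``(0, [])``.
    """
    return _detect_eads_arrays(trace.t, trace.v, theta_rise, v_gate, blank_ms)


def notch_present(trace, min_depth: float = 1.0, search_ms: float = 80.0) -> bool:
    """Phase-1 notch: a local V minimum between the upstroke spike and a
    subsequent dome at least ``min_depth`` mV higher, within ``search_ms``
    of the upstroke."""
    t = np.asarray(trace.t, dtype=float)
    v = np.asarray(trace.v, dtype=float)
    dt = t[1] - t[0]
    iu = _upstroke_index(t, v)
    vs = _smooth(v, dt)
    end = min(vs.size, iu + int(round(search_ms / dt)))
    seg = vs[iu:end]
    if seg.size < 5:
        return False
    minima, maxima = _local_extrema(seg)
    spikes = maxima[maxima < (seg.size - 2)]
    if spikes.size == 0:
        return False
    i_spike = spikes[0]
    for im in minima:
        if im <= i_spike:
            continue
        later_max = maxima[maxima > im]
        if later_max.size == 0:
            continue
        ix = later_max[0]
        depth = seg[i_spike] - seg[im]
        dome = seg[ix] - seg[im]
        if depth >= min_depth and dome >= min_depth:
            return True
    return False


def detect_alternans(apd_series: Sequence[float],
                     ead_counts: Sequence[int] | None = None,
                     theta_alt: float = THETA_ALT,
                     window: int = ALT_WINDOW) -> AlternansReport:
    """Period-2 alternans verdict on the final ``window`` beats.

    ``delta_apd`` is the mean |APD(n) - APD(n-1)| over the window; the APD
    route additionally requires the sign of successive differences to
    alternate in at least 80% of the window.  A period-2 alternation of the
    per-beat EAD count triggers the verdict regardless of APD magnitude.
    """
    a = np.asarray(apd_series, dtype=float)
    if a.size < max(8, window):
        raise ValueError(f"need >= {max(8, window)} beats, got {a.size}")
    w = a[-window:]
    finite = np.isfinite(w)
    if not finite.all():
        # a strictly period-2 pattern of captured / non-repolarizing beats is
        # the extreme large-small AP alternation; anything less regular gets
        # no verdict
        period2_capture = (
            w.size >= 4
            and np.all(finite[::2] == finite[0])
            and np.all(finite[1::2] == finite[1])
            and finite[0] != finite[1]
        )
        if period2_capture:
            return AlternansReport(float("nan"), True,
                                   pattern="alternating repolarization failure",
                                   valid=True)
        return AlternansReport(float("nan"), False,
                               pattern="repolarization failure in window",
                               valid=False)
    diffs = np.diff(w)
    delta = float(np.mean(np.abs(diffs)))
    if diffs.size >= 2:
        signs = np.sign(diffs)
        flips = np.sum(signs[1:] * signs[:-1] < 0)
        consistent = flips >= 0.8 * (diffs.size - 1)
    else:
        consistent = False
    is_alt = bool(delta > theta_alt and consistent)
    pattern = "APD alternation" if is_alt else None

    if ead_counts is not None:
        e = np.asarray(ead_counts, dtype=int)[-window:]
        if e.size >= 4:
            period2 = np.all(e[2:] == e[:-2]) and np.any(e[1:] != e[:-1])
            if period2:
                is_alt = True
                pattern = "EAD-count alternation"
    return AlternansReport(delta, is_alt, pattern=pattern, valid=True)


def ead_onset_cl(curve: RateAdaptationCurve):
    """Slow-rate EAD onset: the smallest sampled CL whose steady-state beats
    show EADs, provided every larger sampled CL does too.

    Returns ``None`` when no CL shows EADs, the onset CL (ms) for the
    monotone slow-rate pattern, and an explicit list of (cl_lo, cl_hi)
    intervals when the pattern is non-monotone.
    """
    cls = curve.cls()
    flags = [curve.points[cl][1] for cl in cls]
    if not any(flags):
        return None
    # contiguous True runs
    runs: list[tuple[float, float]] = []
    start = None
    for cl, fl in zip(cls, flags):
        if fl and start is None:
            start = cl
        elif not fl and start is not None:
            runs.append((start, prev))
            start = None
        prev = cl
    if start is not None:
        runs.append((start, cls[-1]))
    if len(runs) == 1 and runs[0][1] == cls[-1]:
        return runs[0][0]
    return runs


def beat_biomarkers(trace, cl: float | None = None) -> BeatBiomarkers:
    """Bundle of per-beat biomarkers for one trace."""
    a = apd(trace)
    count, times = detect_eads(trace)
    v = np.asarray(trace.v, dtype=float)
    iu = _upstroke_index(np.asarray(trace.t, dtype=float), v)
    v_rest = float(v[0])
    v_peak = float(np.max(v[iu:]))
    return BeatBiomarkers(
        apd90=a, apa=v_peak - v_rest, v_rest=v_rest, v_peak=v_peak,
        ead_count=count, ead_times=times, notch_present=notch_present(trace))
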