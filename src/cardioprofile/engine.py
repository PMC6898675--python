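"""Pacing engine: forward-Euler integration with a two-level adaptive step.

The integrator is forward Euler with an adaptive time step: ``dt_min`` while
the stimulus is on or |dV/dt| exceeds ``dvdt_threshold`` (upstroke), and
``dt_max`` through slow phases.  Steps never cross stimulus, sample-grid or
beat boundaries (time is carried in integer ticks of ``dt_min``).

Pacing runs until either the configured beat budget (default: the full
60-minute schedule at the given cycle length) or a steady-state convergence
rule on the beat-to-beat APD90 series, whichever comes first.  Traces are
sampled on a fixed 0.1 ms output grid regardless of the internal step.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .model_core import (
    CellState,
    IntegrationFailure,
    ModelDef,
    ModelParameters,
    TableSet,
)

logger = logging.getLogger(__name__)

OUTPUT_DT = 0.1          # ms, biomarker sampling grid
PACING_MINUTES = 60.0    # full steady-state schedule length

__all__ = [
    "PacingProtocol",
    "StepController",
    "BeatTrace",
    "PacingResult",
    "step",
    "pace",
    "sweep_cl",
    "write_trace",
    "euler_integrate",
]


@dataclass
class PacingProtocol:
    """Stimulus train description.

    ``stim_amplitude`` is the magnitude (uA/uF) of the depolarizing pulse; the
    engine applies it as an inward (negative) current.  ``None`` defers to the
    calibrated per-cell amplitude stored in the parameter file
    (1.5x diastolic threshold).  ``max_beats=None`` means the full 60-minute
    schedule, ceil(60 min / CL) beats, the upper bound of the convergence rule.
    """

    cl: float                       # cycle length, ms
    stim_amplitude: float | None = None
    stim_duration: float = 0.5      # ms
    max_beats: int | None = None
    ss_window: int = 10             # beats
    ss_tol: float = 0.1             # ms

    def __post_init__(self):
        if not (self.cl >= self.stim_duration > 0):
            raise ValueError(
                f"require CL >= stim_duration > 0 (got CL={self.cl}, "
                f"stim_duration={self.stim_duration})")
        if self.resolved_max_beats() < 1:
            raise ValueError("max_beats must be >= 1")

    def resolved_max_beats(self) -> int:
        if self.max_beats is not None:
            return int(self.max_beats)
        return int(math.ceil(PACING_MINUTES * 60e3 / self.cl))


@dataclass
class StepController:
    """Two-level adaptive step: dt_min during stimulus/upstroke, else dt_max."""

    dt_min: float = 0.001           # ms
    dt_max: float = 0.01            # ms
    dvdt_threshold: float = 1.0     # mV/ms

    def __post_init__(self):
        if not (0 < self.dt_min <= self.dt_max):
            raise ValueError("require 0 < dt_min <= dt_max")
        nsub = self.dt_max / self.dt_min
        if abs(nsub - round(nsub)) > 1e-9:
            raise ValueError("dt_max must be an integer multiple of dt_min")
        if abs(OUTPUT_DT / self.dt_max - round(OUTPUT_DT / self.dt_max)) > 1e-9:
            raise ValueError("dt_max must divide the 0.1 ms output grid")

    @property
    def nsub(self) -> int:
        return int(round(self.dt_max / self.dt_min))


@dataclass
class BeatTrace:
    """One beat on the uniform output grid: time, voltage, currents.

    ``t`` is within-beat time (ms), 0 at stimulus onset, last sample at CL.
    ``currents`` has shape (n_currents, n_samples), outward positive.
    """

    t: np.ndarray
    v: np.ndarray
    currents: np.ndarray
    current_names: list[str]
    beat_index: int
    cl: float
    cai: np.ndarray | None = None

    def current(self, name: str) -> np.ndarray:
        return self.currents[self.current_names.index(name)]

    def to_frame(self):
        import pandas as pd
        data = {"t_ms": self.t, "V_mV": self.v}
        for i, n in enumerate(self.current_names):
            data[f"{n}_uA_per_uF"] = self.currents[i]
        if self.cai is not None:
            data["Ca_i_mM"] = self.cai
        return pd.DataFrame(data)


@dataclass
class PacingResult:
    """Outcome of one pacing run: final traces plus the full APD90 series."""

    beats: list[BeatTrace]
    apd90_series: np.ndarray          # ms; NaN marks repolarization failure
    ead_counts: np.ndarray            # per beat
    converged: bool
    repolarization_failure: bool
    n_beats: int
    cl: float
    max_gate_excursion: float = 0.0
    final_state: CellState | None = None

    @property
    def apd90(self) -> float:
        """Steady-state APD90: mean of the final two beats (alternans-safe)."""
        tail = self.apd90_series[-2:]
        if np.all(np.isnan(tail)):
            return float("nan")
        return float(np.nanmean(tail))


def _stim_signed(protocol: PacingProtocol, params: ModelParameters) -> float:
    amp = protocol.stim_amplitude
    if amp is None:
        amp = params["stim_amplitude"]
    return -abs(float(amp))


def step(state: CellState, params: ModelParameters, i_stim: float,
         controller: StepController, model: ModelDef | None = None,
         stim_active: bool = False) -> tuple[CellState, float]:
    """Single forward-Euler step (python mirror of the kernel arithmetic).

    ``i_stim`` is the signed stimulus current entering dV/dt = -(sum I + i_stim).
    Returns the updated state and the dt actually used.
    """
    from .model_core import get_model, rhs

    model = model or get_model(params.model_name)
    deriv = rhs(state, params, i_stim, model)
    dvdt = deriv["v"]
    use_min = stim_active or abs(dvdt) > controller.dvdt_threshold
    dt = controller.dt_min if use_min else controller.dt_max
    new = state.copy()
    new.v = state.v + dt * dvdt
    if not math.isfinite(new.v):
        raise IntegrationFailure("non-finite V after step", time_ms=state.t)
    for g in new.gates:
        x = state.gates[g] + dt * deriv[g]
        new.gates[g] = min(1.0, max(0.0, x))
    for c in new.concentrations:
        new.concentrations[c] = max(1e-9, state.concentrations[c] + dt * deriv[c])
    new.t = state.t + dt
    return new, dt


def _beat_biomarker_quicklook(t: np.ndarray, v: np.ndarray):
    """Per-beat APD90 + EAD count used by the convergence rule."""
    from .biomarkers import REPOL_FAILURE, apd_from_arrays, ead_count_from_arrays

    try:
        a = apd_from_arrays(t, v, 0.9)
    except ValueError:  # no upstroke (e.g. unstimulated or inexcitable beat)
        return float("nan"), 0
    apd = float("nan") if a is REPOL_FAILURE else float(a)
    return apd, ead_count_from_arrays(t, v)


def _series_converged(apds: list[float], eads: list[int], window: int,
                      tol: float) -> bool:
    if len(apds) < window + 2:
        return False
    a = np.asarray(apds[-(window + 2):])
    e = np.asarray(eads[-(window + 2):])
    if np.any(np.isnan(a)):
        return False
    d1 = np.abs(np.diff(a))[-window:]
    d2 = np.abs(a[2:] - a[:-2])[-window:]
    e1_ok = np.all(e[1:] == e[:-1])
    e2_ok = np.all(e[2:] == e[:-2])
    if np.all(d1 < tol) and e1_ok:
        return True
    # alternans-tolerant: compare beat n with n-2
    if np.all(d2 < tol) and e2_ok:
        return True
    return False


def pace(model: ModelDef, params: ModelParameters, protocol: PacingProtocol,
         controller: StepController | None = None,
         initial_state: CellState | None = None,
         keep_beats: int = 12) -> PacingResult:
    """Pace one cell at fixed cycle length until steady state.

    Pacing stops at the earlier of ``protocol.resolved_max_beats()`` and the
    convergence rule (|APD90(n) - APD90(n-1)| < tol over ``ss_window``
    consecutive beats; with alternans, beat n is compared with beat n-2).
    Returns the final ``keep_beats`` full traces and the APD90 series of every
    beat.  A run in which the membrane stops returning below -60 mV between
    beats is flagged as repolarization failure, not raised.
    """
    controller = controller or StepController()
    tables = model.build_tables(params)
    g_vec = tables.conductance_vector(params)

    state = (initial_state or params.initial_state).copy()
    y = model.state_to_vector(state)

    dt_min = controller.dt_min
    cl_ticks = int(round(protocol.cl / dt_min))
    if cl_ticks * dt_min != protocol.cl and abs(cl_ticks * dt_min - protocol.cl) > 1e-9:
        raise ValueError("CL must be a multiple of dt_min")
    out_every = int(round(OUTPUT_DT / dt_min))
    if cl_ticks % out_every != 0:
        raise ValueError("CL must be a multiple of the 0.1 ms output grid")
    stim_ticks = int(round(protocol.stim_duration / dt_min))
    stim = _stim_signed(protocol, params)

    n_samples = cl_ticks // out_every + 1
    t_grid = OUTPUT_DT * np.arange(n_samples)
    Vout = np.empty(n_samples)
    Iout = np.empty((tables.n_currents, n_samples))
    CaOut = np.empty(n_samples)

    max_beats = protocol.resolved_max_beats()
    apds: list[float] = []
    eads: list[int] = []
    repol_ok: list[bool] = []
    kept: deque[BeatTrace] = deque(maxlen=keep_beats)
    max_exc = 0.0
    converged = False
    repol_failure = False

    for b in range(max_beats):
        status, exc, t_fail = _kernels.integrate_beat(
            y, g_vec, tables.pow, tables.drive, tables.isca, tables.erev,
            tables.rect, tables.caflux, tables.xinf, tables.tau,
            tables.v0, tables.dv, tables.cao, tables.k_ca, tables.tau_ca,
            tables.ca_rest, stim, cl_ticks, stim_ticks, controller.nsub,
            dt_min, controller.dvdt_threshold, out_every, Vout, Iout, CaOut)
        max_exc = max(max_exc, exc)
        if status != _kernels.STATUS_OK:
            raise IntegrationFailure(
                f"non-finite/out-of-range V during beat {b} at t={t_fail:.3f} ms",
                beat_index=b, time_ms=t_fail)

        apd, ead_n = _beat_biomarker_quicklook(t_grid, Vout)
        apds.append(apd)
        eads.append(ead_n)
        kept.append(BeatTrace(t_grid, Vout.copy(), Iout.copy(),
                              list(tables.current_names), b, protocol.cl,
                              CaOut.copy()))

        # repolarization failure: membrane stops reaching rest between beats.
        # transient post-rest adjustment may skip a beat, so only a sustained
        # run (3 consecutive beats) ends pacing early.
        repol_ok.append(float(np.min(Vout)) <= -60.0)
        if len(repol_ok) >= 3 and not any(repol_ok[-3:]):
            repol_failure = True
            logger.warning("sustained repolarization failure at beat %d "
                           "(CL=%g ms)", b, protocol.cl)
            break

        if _series_converged(apds, eads, protocol.ss_window, protocol.ss_tol):
            converged = True
            break

    if max_exc > 1e-6:
        logger.warning("gate excursion %.3e clipped during pacing (CL=%g ms)",
                       max_exc, protocol.cl)

    return PacingResult(
        beats=list(kept),
        apd90_series=np.asarray(apds),
        ead_counts=np.asarray(eads, dtype=int),
        converged=converged,
        repolarization_failure=repol_failure,
        n_beats=len(apds),
        cl=protocol.cl,
        max_gate_excursion=max_exc,
        final_state=model.vector_to_state(y),
    )


def sweep_cl(model: ModelDef, params: ModelParameters,
             cl_list: Sequence[float], controller: StepController | None = None,
             protocol_factory: Callable[[float], PacingProtocol] | None = None,
             keep_beats: int = 12) -> dict[float, PacingResult]:
    """Independent pacing runs across cycle lengths, each from the fresh
    resting state; deterministic given the configuration.

    Per-CL integration failures are carried as ``None`` entries rather than
    aborting the sweep.
    """
    factory = protocol_factory or (lambda cl: PacingProtocol(cl=cl))
    out: dict[float, PacingResult] = {}
    for cl in cl_list:
        try:
            out[float(cl)] = pace(model, params, factory(cl), controller,
                                  keep_beats=keep_beats)
        except IntegrationFailure as err:
            logger.warning("CL=%g ms failed: %s", cl, err)
            out[float(cl)] = None
    return out


def write_trace(trace: BeatTrace, path, beat_column: bool = False) -> None:
    """Write one beat as delimited text (units in the header row)."""
    df = trace.to_frame()
    if beat_column:
        df.insert(0, "beat_index", trace.beat_index)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def euler_integrate(f: Callable[[float, np.ndarray], np.ndarray],
                    y0: np.ndarray, dt: float, t_end: float) -> np.ndarray:
    """Plain fixed-step forward Euler on a generic ODE (integrator oracle)."""
    y = np.asarray(y0, dtype=float).copy()
    n = int(round(t_end / dt))
    t = 0.0
    for _ in range(n):
        y = y + dt * np.asarray(f(t, y))
        t += dt
    return y
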