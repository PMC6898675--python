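"""Synthetic test surfaces: toy EAD-capable cell, parametric AP traces,
randomized drug libraries.

Everything the analysis pipeline consumes can be generated here without the
reference cell family: a fast four-variable plateau-AP model that develops
reactivation EADs when its outward conductance is reduced, piecewise-analytic
voltage traces with implanted EAD humps / alternans / noise and closed-form
ground truth, and schema-valid random compound profiles.  All randomness
flows through one seeded generator per call.

The toy model makes no claim of physiological realism beyond plateau-AP +
reactivation-EAD phenomenology; it exists so the engine, biomarker and
profiling layers are testable in milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .model_core import (
    V_GRID_MAX,
    V_GRID_MIN,
    V_GRID_STEP,
    CellState,
    ModelDef,
    ModelParameters,
    TableSet,
    register_model,
)
from .pharmacology import CHANNEL_PANEL, ChannelBlock, DrugSpec

TOY_MODEL_NAME = "toy-v1"

# Fraction of g_out at which the ead_prone variant sits; reducing g_out
# under ~0.37x nominal tips the plateau into oscillatory reactivation and
# yields >= 1 EAD on every paced beat at slow pacing.
EAD_PRONE_G_OUT_FACTOR = 0.35

TOY_GATES = ["f", "x", "w"]
TOY_CONCENTRATIONS = ["Ca_i"]
TOY_CURRENTS = ["I_in", "I_out", "I_leak"]
TOY_CONDUCTANCES = ["g_in", "g_out", "g_leak"]

# The toy inward current is I_CaL-like and its outward current I_Kr-like, so
# the pharmacology layer maps exactly those two panel channels onto it.
TOY_CHANNEL_MAP = {"Cav1.2": "g_in", "hERG": "g_out"}

TOY_PARAMS = {
    # conductances (mS/uF)
    "g_in": 0.60, "g_out": 0.12, "g_leak": 0.012,
    # reversal potentials (mV)
    "E_in": 45.0, "E_out": -88.0, "E_leak": -84.0,
    # inward activation (instantaneous) and inactivation gate f
    "din_half": -33.0, "din_k": 4.5,
    "f_half": -36.0, "f_k": -5.5,
    "tauf_base": 28.0, "tauf_amp": 220.0, "tauf_c": 10.0, "tauf_w": 30.0,
    # outward activation gate x (fast deactivation in the window region)
    "x_half": -18.0, "x_k": 9.0,
    "taux_base": 60.0, "taux_amp": 350.0, "taux_c": 0.0, "taux_w": 35.0,
    # slow availability gate w (restitution memory; keeps a floor so the
    # late window current survives long plateaus)
    "w_half": -60.0, "w_k": -6.0, "w_floor": 0.4,
    "tauw_base": 90.0, "tauw_amp": 150.0, "tauw_c": -80.0, "tauw_w": 25.0,
    # calcium pool (passive; drives nothing, kept for interface uniformity)
    "Ca_o": 1.8, "k_Ca": 0.0, "tau_Ca": 50.0, "Ca_rest": 2.0e-4,
    # calibrated stimulus amplitude (1.5x diastolic threshold at CL=1000)
    "stim_amplitude": 90.0,
}


def _sig(v, half, k):
    return 1.0 / (1.0 + np.exp(-(v - half) / k))


def _bell(v, base, amp, center, width):
    return base + amp * np.exp(-(((v - center) / width) ** 2))


def _toy_kinetic_key(params: ModelParameters) -> tuple:
    keys = sorted(k for k in TOY_PARAMS
                  if k not in TOY_CONDUCTANCES and k != "stim_amplitude")
    return tuple((k, float(params[k])) for k in keys)


@lru_cache(maxsize=8)
def _toy_tables_cached(key: tuple) -> TableSet:
    p = dict(key)
    n = int(round((V_GRID_MAX - V_GRID_MIN) / V_GRID_STEP)) + 1
    v = V_GRID_MIN + V_GRID_STEP * np.arange(n)

    xinf = np.empty((3, n))
    tau = np.empty((3, n))
    xinf[0] = _sig(v, p["f_half"], p["f_k"])
    tau[0] = _bell(v, p["tauf_base"], p["tauf_amp"], p["tauf_c"], p["tauf_w"])
    xinf[1] = _sig(v, p["x_half"], p["x_k"])
    tau[1] = _bell(v, p["taux_base"], p["taux_amp"], p["taux_c"], p["taux_w"])
    xinf[2] = p["w_floor"] + (1.0 - p["w_floor"]) * _sig(v, p["w_half"], p["w_k"])
    tau[2] = _bell(v, p["tauw_base"], p["tauw_amp"], p["tauw_c"], p["tauw_w"])

    rect = np.ones((3, n))
    rect[0] = _sig(v, p["din_half"], p["din_k"])   # instantaneous activation

    pow_ = np.zeros((3, 3), dtype=np.int64)
    pow_[0, 0] = 1   # I_in ~ f
    pow_[0, 2] = 1   # I_in ~ w
    pow_[1, 1] = 1   # I_out ~ x

    drive = np.ones(3, dtype=np.int8)
    isca = np.zeros(3, dtype=np.int8)
    erev = np.array([p["E_in"], p["E_out"], p["E_leak"]])
    caflux = np.zeros(3)

    return TableSet(
        gate_names=list(TOY_GATES), current_names=list(TOY_CURRENTS),
        conductance_names=list(TOY_CONDUCTANCES),
        xinf=xinf, tau=tau, rect=rect, pow=pow_, drive=drive, isca=isca,
        erev=erev, caflux=caflux,
        cao=p["Ca_o"], k_ca=p["k_Ca"], tau_ca=p["tau_Ca"], ca_rest=p["Ca_rest"],
    )


def _toy_build_tables(params: ModelParameters) -> TableSet:
    return _toy_tables_cached(_toy_kinetic_key(params))


TOY_MODEL = ModelDef(
    name=TOY_MODEL_NAME,
    gate_names=list(TOY_GATES),
    concentration_names=list(TOY_CONCENTRATIONS),
    build_tables=_toy_build_tables,
)

register_model(TOY_MODEL)


def _toy_rest_state(params: ModelParameters) -> CellState:
    # resting point: V pinned near E_leak/E_out by leak; gates at steady state
    v = -83.0
    tbl = _toy_build_tables(params)
    gates = {}
    idx = int(round((v - tbl.v0) / tbl.dv))
    for i, g in enumerate(TOY_GATES):
        gates[g] = float(tbl.xinf[i, idx])
    return CellState(v=v, gates=gates, concentrations={"Ca_i": params["Ca_rest"]})


def make_toy_cell(variant: str = "normal") -> tuple[ModelParameters, CellState]:
    """Toy cell parameter set + resting state.

    ``variant='normal'`` produces a plateau AP (APD90 in 150-400 ms at
    CL = 1000 ms) with no EADs; ``variant='ead_prone'`` differs only in a
    reduced outward conductance and develops at least one EAD per beat at
    slow pacing.  Both share the same state layout.
    """
    if variant not in ("normal", "ead_prone"):
        raise ValueError(f"unknown toy variant {variant!r}; "
                         "expected 'normal' or 'ead_prone'")
    vals = dict(TOY_PARAMS)
    if variant == "ead_prone":
        vals["g_out"] = vals["g_out"] * EAD_PRONE_G_OUT_FACTOR
    params = ModelParameters(TOY_MODEL_NAME, vals, cell_type=None,
                             channel_map=TOY_CHANNEL_MAP)
    state = _toy_rest_state(params)
    params.initial_state = state.copy()
    return params, state


# ---------------------------------------------------------------------------
# Parametric AP traces with implanted events
# ---------------------------------------------------------------------------

@dataclass
class SyntheticAPSpec:
    """Recipe for a piecewise-analytic AP trace with known ground truth.

    The clean trace is: rest until ``t_up``, linear upstroke of 1 ms to
    ``v_peak``, optional phase-1 notch (cosine dip), then a linear descent
    reaching ``v_rest`` at ``t_up + 1 + descent``; EAD events are cosine-bump
    humps (time, amplitude mV, width ms) added on the descent.  Gaussian
    noise of ``noise_sd`` mV is added last (ground truth is pre-noise).
    """

    v_rest: float = -85.0
    v_peak: float = 40.0
    apd: float = 300.0            # descent duration, ms
    cl: float = 1000.0
    t_up: float = 2.0
    notch_depth: float = 0.0      # mV
    ead_events: list[tuple[float, float, float]] = field(default_factory=list)
    alternans_delta: float = 0.0  # period-2 APD delta for series generation
    noise_sd: float = 0.0
    seed: int = 0

    RISE_MS = 1.0
    NOTCH_WIDTH = 14.0

    def analytic_apd90(self) -> float:
        # descent is linear from v_peak to v_rest: the 90%-repolarization
        # level is crossed 0.9 * descent after the peak; measured from the
        # max-dV/dt sample (start of the linear rise), the rise adds RISE_MS
        return 0.9 * self.apd + self.RISE_MS

    def validate(self) -> None:
        if self.v_peak <= self.v_rest:
            raise ValueError("v_peak must exceed v_rest")
        t_peak = self.t_up + self.RISE_MS
        for (t_e, amp, width) in self.ead_events:
            if not (t_peak + width / 2 < t_e < t_peak + self.apd):
                raise ValueError(
                    f"EAD event at t={t_e} ms lies outside the AP span "
                    f"({t_peak:.1f}, {t_peak + self.apd:.1f}) ms")
            if amp <= 0 or width <= 0:
                raise ValueError("EAD amplitude and width must be positive")
        if self.apd + self.t_up + self.RISE_MS >= self.cl:
            raise ValueError("AP does not fit inside the cycle length")


def synth_ap_trace(spec: SyntheticAPSpec):
    """Generate one synthetic beat.

    Returns ``(trace, truth)`` where ``truth`` carries the closed-form
    pre-noise APD90 and the implanted EAD times.
    """
    from .engine import OUTPUT_DT, BeatTrace

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.cl / OUTPUT_DT)) + 1
    t = OUTPUT_DT * np.arange(n)
    v = np.full(n, spec.v_rest, dtype=float)

    t_peak = spec.t_up + spec.RISE_MS
    t_end = t_peak + spec.apd

    rise = (t >= spec.t_up) & (t < t_peak)
    v[rise] = spec.v_rest + (spec.v_peak - spec.v_rest) * (
        (t[rise] - spec.t_up) / spec.RISE_MS)

    desc = (t >= t_peak) & (t < t_end)
    v[desc] = spec.v_peak + (spec.v_rest - spec.v_peak) * (
        (t[desc] - t_peak) / spec.apd)

    if spec.notch_depth > 0:
        sel = (t >= t_peak) & (t < t_peak + spec.NOTCH_WIDTH)
        phase = (t[sel] - t_peak) / spec.NOTCH_WIDTH
        v[sel] -= spec.notch_depth * np.sin(np.pi * phase) ** 2

    for (t_e, amp, width) in spec.ead_events:
        sel = (t >= t_e - width / 2) & (t < t_e + width / 2)
        phase = (t[sel] - (t_e - width / 2)) / width
        v[sel] += amp * np.sin(np.pi * phase) ** 2

    clean = v.copy()
    if spec.noise_sd > 0:
        v = v + rng.normal(0.0, spec.noise_sd, size=n)

    trace = BeatTrace(t=t, v=v, currents=np.zeros((0, n)), current_names=[],
                      beat_index=0, cl=spec.cl)
    truth = {
        "apd90": spec.analytic_apd90(),
        "ead_times": [t_e for (t_e, _, _) in spec.ead_events],
        "clean_v": clean,
    }
    return trace, truth


def synth_ap_series(spec: SyntheticAPSpec, n_beats: int):
    """Period-2 alternans series: beats alternate APD +/- alternans_delta/2.

    Returns (traces, apd90_truths).
    """
    traces, truths = [], []
    for b in range(n_beats):
        delta = spec.alternans_delta / 2.0 * (1 if b % 2 == 0 else -1)
        bspec = SyntheticAPSpec(
            v_rest=spec.v_rest, v_peak=spec.v_peak, apd=spec.apd + delta,
            cl=spec.cl, t_up=spec.t_up, notch_depth=spec.notch_depth,
            ead_events=list(spec.ead_events), noise_sd=spec.noise_sd,
            seed=spec.seed + b)
        tr, truth = synth_ap_trace(bspec)
        tr.beat_index = b
        traces.append(tr)
        truths.append(truth["apd90"])
    return traces, truths


# ---------------------------------------------------------------------------
# Randomized drug libraries
# ---------------------------------------------------------------------------

def synth_drug_library(n: int, seed: int = 0,
                       channels: tuple[str, ...] = CHANNEL_PANEL) -> list[DrugSpec]:
    """``n`` schema-valid random compounds.

    Per channel: IC50 log-uniform over [0.01, 100] uM, Hill uniform over
    [0.5, 2]; EFTPC log-uniform over [0.001, 10] uM.  Reproducible per seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[DrugSpec] = []
    for i in range(n):
        eftpc = float(10 ** rng.uniform(-3, 1))
        blocks = {}
        for ch in channels:
            ic50 = float(10 ** rng.uniform(-2, 2))
            hill = float(rng.uniform(0.5, 2.0))
            blocks[ch] = ChannelBlock(ic50=ic50, hill=hill)
        out.append(DrugSpec(name=f"synthetic-{i:03d}", eftpc=eftpc,
                            blocks=blocks))
    return out
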