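"""Reference four-cell-type family: Hodgkin-Huxley current formulations.

A compact ionic model carrying the currents the CiPA channel panel targets
(I_Na, I_NaL, I_CaL, I_Kr, I_Ks, I_to, I_K1) plus Na/K pump and background
currents.  The four cell types (Purkinje, Endo, M, Epi) share these equations
and differ only in maximal conductances, following the documented transmural /
Purkinje heterogeneities: M cells carry a larger I_NaL and a smaller I_Ks
(reduced repolarization reserve); Endo cells a much smaller I_to (no phase-1
notch); Purkinje cells a large I_NaL, a small I_CaL and a larger I_Na
(higher amplitude, longest APD, steep rate adaptation at short cycle length).

Gate kinetics use the relaxation form dx/dt = (x_inf(V) - x)/tau_x(V) with
sigmoidal steady states and Gaussian-bell time constants; all V-dependent
terms are tabulated on a 0.02 mV grid for the engine kernel.

Intracellular calcium is a single pool driven by the Ca-carrying currents and
relaxing to its diastolic level; it feeds the Ca Nernst potential only.  No
SR release/uptake machinery is represented.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .model_core import (
    RTF,
    V_GRID_MAX,
    V_GRID_MIN,
    V_GRID_STEP,
    ModelDef,
    ModelParameters,
    TableSet,
    register_model,
)

MODEL_NAME = "family-v1"

GATES = ["m", "h", "j", "mL", "hL", "d", "f", "xr", "xs", "r", "s"]
CONCENTRATIONS = ["Ca_i"]

CURRENTS = ["I_Na", "I_NaL", "I_CaL", "I_Kr", "I_Ks", "I_to",
            "I_K1", "I_NaK", "I_bNa", "I_bCa"]
CONDUCTANCES = ["g_Na", "g_NaL", "g_CaL", "g_Kr", "g_Ks", "g_to",
                "g_K1", "p_NaK", "g_bNa", "g_bCa"]

# Pharmacology channel panel -> conductance mapping for this family.
CHANNEL_MAP = {
    "Nav1.5-peak": "g_Na",
    "Nav1.5-late": "g_NaL",
    "Cav1.2": "g_CaL",
    "hERG": "g_Kr",
    "Kv4.3": "g_to",
    "KCNQ1/KCNE1": "g_Ks",
    "Kir2.1": "g_K1",
}


def _sig(v, half, k):
    return 1.0 / (1.0 + np.exp(-(v - half) / k))


def _bell(v, base, amp, center, width):
    return base + amp * np.exp(-(((v - center) / width) ** 2))


def _grid() -> np.ndarray:
    n = int(round((V_GRID_MAX - V_GRID_MIN) / V_GRID_STEP)) + 1
    return V_GRID_MIN + V_GRID_STEP * np.arange(n)


# Kinetic constants are parameters so that every constant lives in the
# per-cell parameter file; the keys below are (half, slope) of the sigmoids
# and (base, amp, center, width) of the time-constant bells.
KINETIC_DEFAULTS = {
    # fast Na activation/inactivation (m ~10x faster than h so the spike is
    # regenerative before inactivation catches up)
    "m_half": -40.0, "m_k": 6.5, "taum_base": 0.03, "taum_amp": 0.12,
    "taum_c": -45.0, "taum_w": 15.0,
    "h_half": -70.0, "h_k": -6.0, "tauh_base": 0.7, "tauh_amp": 6.0,
    "tauh_c": -52.0, "tauh_w": 16.0,
    "tauj_base": 2.5, "tauj_amp": 35.0, "tauj_c": -70.0, "tauj_w": 20.0,
    # late Na
    "mL_half": -43.0, "mL_k": 5.3, "taumL_base": 0.6, "taumL_amp": 1.5,
    "taumL_c": -40.0, "taumL_w": 20.0,
    # hL keeps a small non-inactivating pedestal (persistent late Na)
    "hL_half": -76.0, "hL_k": -7.0, "hL_floor": 0.10,
    "tauhL_base": 300.0, "tauhL_amp": 280.0,
    "tauhL_c": -80.0, "tauhL_w": 30.0,
    # L-type Ca; fixed effective reversal potential (GHK flux flattening)
    "d_half": -17.0, "d_k": 6.2, "taud_base": 0.6, "taud_amp": 4.5,
    "taud_c": -15.0, "taud_w": 15.0,
    "f_half": -26.0, "f_k": -6.2, "tauf_base": 40.0, "tauf_amp": 160.0,
    "tauf_c": 30.0, "tauf_w": 30.0,
    # slow diastolic recovery component of f (restitution memory)
    "tauf2_amp": 260.0, "tauf2_c": -85.0, "tauf2_w": 30.0,
    "E_CaL": 48.0,
    # rapid delayed rectifier (activation gate + instantaneous rectification)
    "xr_half": -20.0, "xr_k": 7.5, "tauxr_base": 40.0, "tauxr_amp": 350.0,
    "tauxr_c": -35.0, "tauxr_w": 25.0,
    "rkr_half": 5.0, "rkr_k": -30.0,
    # slow delayed rectifier; second tau component slows diastolic
    # deactivation so I_Ks accumulates at fast rates (rate adaptation)
    "xs_half": -8.0, "xs_k": 13.0, "tauxs_base": 120.0, "tauxs_amp": 400.0,
    "tauxs_c": 0.0, "tauxs_w": 40.0,
    "tauxs2_amp": 700.0, "tauxs2_c": -85.0, "tauxs2_w": 25.0,
    # transient outward
    "r_half": 12.0, "r_k": 11.0, "taur_base": 1.0, "taur_amp": 3.0,
    "taur_c": -20.0, "taur_w": 25.0,
    "s_half": -33.0, "s_k": -6.0, "taus_base": 8.0, "taus_amp": 40.0,
    "taus_c": -50.0, "taus_w": 18.0,
    # inward rectifier and pump voltage dependence
    "k1_half": -75.0, "k1_k": -9.0,
    "fnak_half": -70.0, "fnak_k": 25.0,
    # ion concentrations (fixed) and Ca pool dynamics
    "Na_o": 140.0, "Na_i": 10.0, "K_o": 5.4, "K_i": 145.0, "Ca_o": 1.8,
    "k_Ca": 3.0e-6, "tau_Ca": 70.0, "Ca_rest": 2.0e-4,
}


def _kinetic_key(params: ModelParameters) -> tuple:
    return tuple(float(params[k]) for k in sorted(KINETIC_DEFAULTS))


@lru_cache(maxsize=16)
def _build_tables_cached(key: tuple) -> TableSet:
    p = dict(zip(sorted(KINETIC_DEFAULTS), key))
    v = _grid()
    nV = v.size

    e_na = RTF * math.log(p["Na_o"] / p["Na_i"])
    e_k = RTF * math.log(p["K_o"] / p["K_i"])

    xinf = np.empty((len(GATES), nV))
    tau = np.empty((len(GATES), nV))

    xinf[0] = _sig(v, p["m_half"], p["m_k"])
    tau[0] = _bell(v, p["taum_base"], p["taum_amp"], p["taum_c"], p["taum_w"])
    xinf[1] = _sig(v, p["h_half"], p["h_k"])
    tau[1] = _bell(v, p["tauh_base"], p["tauh_amp"], p["tauh_c"], p["tauh_w"])
    xinf[2] = xinf[1]  # j shares h_inf, slower tau
    tau[2] = _bell(v, p["tauj_base"], p["tauj_amp"], p["tauj_c"], p["tauj_w"])
    xinf[3] = _sig(v, p["mL_half"], p["mL_k"])
    tau[3] = _bell(v, p["taumL_base"], p["taumL_amp"], p["taumL_c"], p["taumL_w"])
    xinf[4] = p["hL_floor"] + (1.0 - p["hL_floor"]) * _sig(v, p["hL_half"], p["hL_k"])
    tau[4] = _bell(v, p["tauhL_base"], p["tauhL_amp"], p["tauhL_c"], p["tauhL_w"])
    xinf[5] = _sig(v, p["d_half"], p["d_k"])
    tau[5] = _bell(v, p["taud_base"], p["taud_amp"], p["taud_c"], p["taud_w"])
    xinf[6] = _sig(v, p["f_half"], p["f_k"])
    tau[6] = (_bell(v, p["tauf_base"], p["tauf_amp"], p["tauf_c"], p["tauf_w"])
              + _bell(v, 0.0, p["tauf2_amp"], p["tauf2_c"], p["tauf2_w"]))
    xinf[7] = _sig(v, p["xr_half"], p["xr_k"])
    tau[7] = _bell(v, p["tauxr_base"], p["tauxr_amp"], p["tauxr_c"], p["tauxr_w"])
    xinf[8] = _sig(v, p["xs_half"], p["xs_k"])
    tau[8] = (_bell(v, p["tauxs_base"], p["tauxs_amp"], p["tauxs_c"], p["tauxs_w"])
              + _bell(v, 0.0, p["tauxs2_amp"], p["tauxs2_c"], p["tauxs2_w"]))
    xinf[9] = _sig(v, p["r_half"], p["r_k"])
    tau[9] = _bell(v, p["taur_base"], p["taur_amp"], p["taur_c"], p["taur_w"])
    xinf[10] = _sig(v, p["s_half"], p["s_k"])
    tau[10] = _bell(v, p["taus_base"], p["taus_amp"], p["taus_c"], p["taus_w"])

    nC = len(CURRENTS)
    rect = np.ones((nC, nV))
    pow_ = np.zeros((nC, len(GATES)), dtype=np.int64)
    drive = np.ones(nC, dtype=np.int8)
    isca = np.zeros(nC, dtype=np.int8)
    erev = np.zeros(nC)
    caflux = np.zeros(nC)

    gi = {g: i for i, g in enumerate(GATES)}
    ci = {c: i for i, c in enumerate(CURRENTS)}

    # I_Na = g_Na m^3 h j (V - E_Na)
    pow_[ci["I_Na"], gi["m"]] = 3
    pow_[ci["I_Na"], gi["h"]] = 1
    pow_[ci["I_Na"], gi["j"]] = 1
    erev[ci["I_Na"]] = e_na
    # I_NaL = g_NaL mL hL (V - E_Na)
    pow_[ci["I_NaL"], gi["mL"]] = 1
    pow_[ci["I_NaL"], gi["hL"]] = 1
    erev[ci["I_NaL"]] = e_na
    # I_CaL = g_CaL d f (V - E_CaL), fixed effective reversal
    pow_[ci["I_CaL"], gi["d"]] = 1
    pow_[ci["I_CaL"], gi["f"]] = 1
    erev[ci["I_CaL"]] = p["E_CaL"]
    caflux[ci["I_CaL"]] = 1.0
    # I_Kr = g_Kr xr rkr(V) (V - E_K)
    pow_[ci["I_Kr"], gi["xr"]] = 1
    rect[ci["I_Kr"]] = _sig(v, p["rkr_half"], p["rkr_k"])
    erev[ci["I_Kr"]] = e_k
    # I_Ks = g_Ks xs^2 (V - E_K)
    pow_[ci["I_Ks"], gi["xs"]] = 2
    erev[ci["I_Ks"]] = e_k
    # I_to = g_to r s (V - E_K)
    pow_[ci["I_to"], gi["r"]] = 1
    pow_[ci["I_to"], gi["s"]] = 1
    erev[ci["I_to"]] = e_k
    # I_K1 = g_K1 k1inf(V) (V - E_K)
    rect[ci["I_K1"]] = _sig(v, p["k1_half"], p["k1_k"])
    erev[ci["I_K1"]] = e_k
    # I_NaK = p_NaK fnak(V)  (no driving-force factor)
    rect[ci["I_NaK"]] = _sig(v, p["fnak_half"], p["fnak_k"])
    drive[ci["I_NaK"]] = 0
    # backgrounds
    erev[ci["I_bNa"]] = e_na
    isca[ci["I_bCa"]] = 1
    caflux[ci["I_bCa"]] = 1.0

    return TableSet(
        gate_names=list(GATES), current_names=list(CURRENTS),
        conductance_names=list(CONDUCTANCES),
        xinf=xinf, tau=tau, rect=rect, pow=pow_, drive=drive, isca=isca,
        erev=erev, caflux=caflux,
        cao=p["Ca_o"], k_ca=p["k_Ca"], tau_ca=p["tau_Ca"], ca_rest=p["Ca_rest"],
    )


def build_tables(params: ModelParameters) -> TableSet:
    return _build_tables_cached(_kinetic_key(params))


FAMILY_MODEL = ModelDef(
    name=MODEL_NAME,
    gate_names=list(GATES),
    concentration_names=list(CONCENTRATIONS),
    build_tables=build_tables,
)

register_model(FAMILY_MODEL)


def base_parameter_values(conductances: dict[str, float]) -> dict[str, float]:
    """Full parameter dict: shared kinetics + the given maximal conductances."""
    vals = dict(KINETIC_DEFAULTS)
    vals.update(conductances)
    missing = [c for c in CONDUCTANCES if c not in vals]
    if missing:
        raise ValueError(f"missing conductances: {missing}")
    return vals
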