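"""Single-cell cardiac ionic models: cell-type family, parameters, state, currents.

The package ships a four-member family of single-cell action-potential models
(Purkinje, endocardial, mid-myocardial, epicardial) built from
Hodgkin-Huxley-style gated currents, plus a fast four-variable toy model
(see :mod:`cardioprofile.synthetic_fixtures`).  Both sit behind the same
pluggable interface (:class:`ModelDef`) so the pacing engine, pharmacology and
biomarker layers are agnostic of which family is in use.

Units, repository-wide: voltage mV, time ms, concentration mM, current
density uA/uF.  Sign convention: outward current positive, and

    dV/dt = -(sum(I_ion) + i_stim)

so a depolarizing stimulus enters with a negative sign.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CellType",
    "CellState",
    "CurrentSet",
    "ModelParameters",
    "ModelDef",
    "TableSet",
    "IntegrationFailure",
    "make_cell",
    "compute_currents",
    "rhs",
    "load_parameter_file",
    "save_parameter_file",
]

# Voltage grid on which all rate functions are tabulated (linear interpolation
# in between).  0.02 mV resolution keeps the tabulation error far below the
# forward-Euler discretisation error.
V_GRID_MIN = -150.0
V_GRID_MAX = 80.0
V_GRID_STEP = 0.02

# Physical constant RT/F at 310 K, in mV.
RTF = 26.712


class CellType(str, Enum):
    """The four members of the cell family."""

    PURKINJE = "Purkinje"
    ENDO = "Endo"
    M = "M"
    EPI = "Epi"

    @classmethod
    def parse(cls, label: str) -> "CellType":
        for ct in cls:
            if ct.value.lower() == str(label).lower():
                return ct
        raise ValueError(
            f"unknown cell type {label!r}; expected one of "
            f"{[ct.value for ct in cls]}"
        )


class IntegrationFailure(RuntimeError):
    """Raised when a state or current becomes non-finite during integration."""

    def __init__(self, message: str, beat_index: int | None = None,
                 time_ms: float | None = None):
        super().__init__(message)
        self.beat_index = beat_index
        self.time_ms = time_ms


@dataclass
class CellState:
    """Instantaneous state of one cell.

    ``gates`` holds the dimensionless activation/inactivation variables (each
    in [0, 1]); ``concentrations`` the intracellular ion concentrations in mM
    (each > 0).
    """

    v: float
    gates: dict[str, float]
    concentrations: dict[str, float]
    t: float = 0.0

    def validate(self) -> None:
        if not (-150.0 < self.v < 80.0):
            raise ValueError(f"membrane potential {self.v} mV outside (-150, 80)")
        for name, x in self.gates.items():
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"gate {name}={x} outside [0, 1]")
        for name, c in self.concentrations.items():
            if not c > 0:
                raise ValueError(f"concentration {name}={c} not positive")

    def copy(self) -> "CellState":
        return CellState(self.v, dict(self.gates), dict(self.concentrations), self.t)


@dataclass
class CurrentSet:
    """Named membrane current densities (uA/uF), outward positive."""

    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def total(self) -> float:
        return float(sum(self.values.values()))

    def names(self) -> list[str]:
        return list(self.values)


class ModelParameters(Mapping):
    """Immutable named parameter set (conductances, kinetics, initial state).

    Behaves as a read-only mapping name -> float for the scalar constants.
    ``channel_map`` ties pharmacology channel labels to conductance names.
    """

    def __init__(self, model_name: str, values: Mapping[str, float],
                 cell_type: CellType | None = None,
                 channel_map: Mapping[str, str] | None = None,
                 initial_state: CellState | None = None):
        self.model_name = model_name
        self.cell_type = cell_type
        self._values = dict(values)
        self.channel_map = dict(channel_map or {})
        self.initial_state = initial_state
        for k, v in self._values.items():
            if k.startswith(("g_", "p_")) and v < 0:
                raise ValueError(f"conductance {k}={v} must be >= 0")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    # ----------------------------------------------------------------------
    def replace(self, **updates: float) -> "ModelParameters":
        vals = dict(self._values)
        for k, v in updates.items():
            if k not in vals:
                raise KeyError(f"unknown parameter {k!r}")
            vals[k] = v
        return ModelParameters(self.model_name, vals, self.cell_type,
                               self.channel_map, self.initial_state)

    def scaled(self, name: str, factor: float) -> "ModelParameters":
        return self.replace(**{name: self._values[name] * factor})

    def checksum(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        d = {
            "model": self.model_name,
            "cell_type": self.cell_type.value if self.cell_type else None,
            "parameters": dict(self._values),
            "channel_map": dict(self.channel_map),
        }
        if self.initial_state is not None:
            d["initial_state"] = {
                "v": self.initial_state.v,
                "gates": dict(self.initial_state.gates),
                "concentrations": dict(self.initial_state.concentrations),
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        init = None
        if d.get("initial_state"):
            s = d["initial_state"]
            init = CellState(float(s["v"]),
                             {k: float(v) for k, v in s["gates"].items()},
                             {k: float(v) for k, v in s["concentrations"].items()})
        ct = CellType.parse(d["cell_type"]) if d.get("cell_type") else None
        return cls(d["model"], {k: float(v) for k, v in d["parameters"].items()},
                   ct, d.get("channel_map") or {}, init)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ModelParameters)
                and self.to_dict() == other.to_dict())

    def __repr__(self) -> str:
        ct = self.cell_type.value if self.cell_type else "generic"
        return f"ModelParameters({self.model_name}, {ct}, {len(self._values)} constants)"


@dataclass
class TableSet:
    """Tabulated kinetics and current topology consumed by the engine kernel.

    Current i is evaluated as

        I_i = G[i] * prod_g gate[g]**POW[i, g] * RECT_i(V) * drive

    where drive is (V - EREV[i]) if DRIVE[i], the calcium Nernst driving force
    if ISCA[i], and 1 otherwise.  RECT holds voltage-dependent multiplicative
    factors (instantaneous gates, rectification, pump voltage dependence).
    """

    gate_names: list[str]
    current_names: list[str]
    conductance_names: list[str]          # parameter name feeding G, per current
    xinf: np.ndarray                      # (n_gates, nV)
    tau: np.ndarray                       # (n_gates, nV)
    rect: np.ndarray                      # (n_currents, nV)
    pow: np.ndarray                       # (n_currents, n_gates) int64
    drive: np.ndarray                     # (n_currents,) int8: 1 ohmic, 0 none
    isca: np.ndarray                      # (n_currents,) int8: Ca Nernst drive
    erev: np.ndarray                      # (n_currents,) mV
    caflux: np.ndarray                    # (n_currents,) Ca-flux weight
    cao: float
    k_ca: float                           # mM per (uA/uF * ms)
    tau_ca: float                         # ms
    ca_rest: float                        # mM
    v0: float = V_GRID_MIN
    dv: float = V_GRID_STEP

    @property
    def n_gates(self) -> int:
        return len(self.gate_names)

    @property
    def n_currents(self) -> int:
        return len(self.current_names)

    def conductance_vector(self, params: ModelParameters) -> np.ndarray:
        return np.array([params[n] for n in self.conductance_names], dtype=np.float64)


@dataclass
class ModelDef:
    """Pluggable model interface: state layout + kinetics tables + parameters.

    ``build_tables(params)`` returns the :class:`TableSet` the engine kernel
    integrates; it depends only on kinetic constants, never on conductances,
    so drug-scaled parameter sets reuse the same tables.
    """

    name: str
    gate_names: list[str]
    concentration_names: list[str]
    build_tables: Callable[[ModelParameters], TableSet]

    def state_to_vector(self, state: CellState) -> np.ndarray:
        y = np.empty(1 + len(self.gate_names) + len(self.concentration_names))
        y[0] = state.v
        for i, g in enumerate(self.gate_names):
            y[1 + i] = state.gates[g]
        for i, c in enumerate(self.concentration_names):
            y[1 + len(self.gate_names) + i] = state.concentrations[c]
        return y

    def vector_to_state(self, y: np.ndarray, t: float = 0.0) -> CellState:
        ng = len(self.gate_names)
        return CellState(
            float(y[0]),
            {g: float(y[1 + i]) for i, g in enumerate(self.gate_names)},
            {c: float(y[1 + ng + i]) for i, c in enumerate(self.concentration_names)},
            t,
        )


# ---------------------------------------------------------------------------
# Evaluation helpers (pure-python mirror of the engine kernel arithmetic).
# ---------------------------------------------------------------------------

def _lerp(table: np.ndarray, v: float, v0: float, dv: float) -> float:
    x = (v - v0) / dv
    n = table.shape[-1]
    if x <= 0.0:
        return float(table[..., 0]) if table.ndim == 1 else table[..., 0]
    if x >= n - 1:
        return float(table[..., n - 1])
    i = int(x)
    w = x - i
    return float(table[..., i] * (1.0 - w) + table[..., i + 1] * w)


def _current_values(y: np.ndarray, tables: TableSet, g_vec: np.ndarray) -> np.ndarray:
    v = float(y[0])
    ng = tables.n_gates
    cai = float(y[1 + ng])
    e_ca = 0.5 * RTF * math.log(tables.cao / cai)
    out = np.empty(tables.n_currents)
    for c in range(tables.n_currents):
        val = g_vec[c] * _lerp(tables.rect[c], v, tables.v0, tables.dv)
        for g in range(ng):
            p = int(tables.pow[c, g])
            if p:
                val *= float(y[1 + g]) ** p
        if tables.isca[c]:
            val *= (v - e_ca)
        elif tables.drive[c]:
            val *= (v - tables.erev[c])
        out[c] = val
    return out


def compute_currents(state: CellState, params: ModelParameters,
                     model: ModelDef | None = None) -> CurrentSet:
    """Evaluate every membrane current at ``state`` (uA/uF, outward positive).

    Currents whose maximal conductance is zero are exactly zero.  Non-finite
    values raise :class:`IntegrationFailure` naming the offending current.
    """
    model = model or get_model(params.model_name)
    state.validate()
    tables = model.build_tables(params)
    y = model.state_to_vector(state)
    vals = _current_values(y, tables, tables.conductance_vector(params))
    out = {}
    for name, v in zip(tables.current_names, vals):
        if not math.isfinite(v):
            raise IntegrationFailure(
                f"current {name} is non-finite at V={state.v:.3f} mV",
                time_ms=state.t)
        out[name] = float(v)
    return CurrentSet(out)


def rhs(state: CellState, params: ModelParameters, i_stim: float = 0.0,
        model: ModelDef | None = None) -> dict[str, float]:
    """Time derivative of the full state.

    dV/dt = -(sum(I_ion) + i_stim); gates relax to their tabulated steady
    state with the tabulated time constant; the intracellular Ca pool follows
    the model's flux-relaxation balance.
    """
    if not math.isfinite(i_stim):
        raise ValueError("i_stim must be finite")
    model = model or get_model(params.model_name)
    tables = model.build_tables(params)
    y = model.state_to_vector(state)
    vals = _current_values(y, tables, tables.conductance_vector(params))
    if not np.all(np.isfinite(vals)):
        bad = tables.current_names[int(np.argmax(~np.isfinite(vals)))]
        raise IntegrationFailure(
            f"current {bad} is non-finite at V={state.v:.3f} mV", time_ms=state.t)
    v = state.v
    deriv: dict[str, float] = {"v": -(float(vals.sum()) + i_stim)}
    for g_i, gname in enumerate(tables.gate_names):
        xinf = _lerp(tables.xinf[g_i], v, tables.v0, tables.dv)
        tau = _lerp(tables.tau[g_i], v, tables.v0, tables.dv)
        deriv[gname] = (xinf - state.gates[gname]) / tau
    cai = state.concentrations["Ca_i"]
    caflux = float(np.dot(tables.caflux, vals))
    deriv["Ca_i"] = -tables.k_ca * caflux - (cai - tables.ca_rest) / tables.tau_ca
    return deriv


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

def save_parameter_file(params: ModelParameters, path) -> None:
    """Write a parameter set as structured YAML (units declared in header)."""
    header = (
        "# cardioprofile parameter file\n"
        "# units: voltage mV, time ms, concentration mM, conductance mS/uF,\n"
        "#        current density uA/uF; outward current positive\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)


def load_parameter_file(path) -> ModelParameters:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ModelParameters.from_dict(d)


# ---------------------------------------------------------------------------
# Model registry and cell factory
# ---------------------------------------------------------------------------

_MODEL_REGISTRY: dict[str, ModelDef] = {}


def register_model(model: ModelDef) -> None:
    _MODEL_REGISTRY[model.name] = model


def get_model(name: str) -> ModelDef:
    try:
        return _MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; registered: {list(_MODEL_REGISTRY)}")


_PARAM_FILES = {
    CellType.PURKINJE: "purkinje.yaml",
    CellType.ENDO: "endo.yaml",
    CellType.M: "mid.yaml",
    CellType.EPI: "epi.yaml",
}


def make_cell(cell_type: CellType | str) -> tuple[ModelParameters, CellState]:
    """Return the parameter set and resting initial state for one cell type.

    Pure function of the shipped per-cell parameter files.  The four sets
    share the same equations and differ in the documented heterogeneity
    scalings (M: larger I_NaL / smaller I_Ks; Endo: reduced I_to; Purkinje:
    larger I_NaL, smaller I_CaL, larger I_Na).
    """
    ct = cell_type if isinstance(cell_type, CellType) else CellType.parse(cell_type)
    fname = _PARAM_FILES[ct]
    ref = resources.files("cardioprofile").joinpath("params", fname)
    with resources.as_file(ref) as p:
        params = load_parameter_file(p)
    if params.initial_state is None:
        raise ValueError(f"parameter file {fname} lacks an initial state")
    return params, params.initial_state.copy()
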