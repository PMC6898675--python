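"""Study orchestration: drug x cell type x cycle-length profiling.

``run_profile`` paces every requested (drug, cell, CL) combination to steady
state alongside a cached drug-free control, extracts the biomarkers
(delta-APD%, EAD flag/count, alternans, dominant EAD depolarizing current)
and assembles a :class:`ProfileTable`.  Per-combination failures are carried
in the table, never aborting the grid; identical configurations produce
bit-identical tables (there is no randomness anywhere in the pipeline).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (
    REPOL_FAILURE,
    RateAdaptationCurve,
    apd,
    beat_biomarkers,
    delta_apd_percent,
    detect_alternans,
    detect_eads,
    ead_onset_cl,
)
from .engine import BeatTrace, PacingProtocol, PacingResult, StepController, pace
from .model_core import CellType, IntegrationFailure, get_model, make_cell
from .pharmacology import DrugSpec, apply_drug

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileConfig",
    "ProfileTable",
    "run_profile",
    "attribute_ead_current",
    "rank_vulnerability",
    "adaptation_curve",
    "DEFAULT_CL_GRID",
]

# 300-2000 ms in 50 ms steps covers every cycle length the study conditions
# cite (300, 550, 1000, 1050, 1800, 2000).
DEFAULT_CL_GRID = tuple(range(300, 2001, 50))


@dataclass
class ProfileConfig:
    """Run configuration; fingerprinted into every output table."""

    dt_min: float = 0.001
    dt_max: float = 0.01
    dvdt_threshold: float = 1.0
    max_beats: int | None = None     # None = full 60-minute schedule bound
    ss_window: int = 10
    ss_tol: float = 0.1              # ms
    keep_beats: int = 12
    theta_rise: float = 2.0          # mV, EAD secondary-rise threshold
    v_gate: float = -40.0            # mV
    theta_alt: float = 5.0           # ms
    conc_scale: float = 1.0          # multiple of EFTPC
    candidate_currents: tuple[str, ...] = ("I_NaL", "I_CaL")
    seed: int = 0                    # recorded for provenance; pipeline is
                                     # deterministic

    def controller(self) -> StepController:
        return StepController(self.dt_min, self.dt_max, self.dvdt_threshold)

    def protocol(self, cl: float) -> PacingProtocol:
        return PacingProtocol(cl=cl, max_beats=self.max_beats,
                              ss_window=self.ss_window, ss_tol=self.ss_tol)


@dataclass
class ProfileTable:
    """Grid of per-combination biomarkers plus the run fingerprint."""

    df: pd.DataFrame
    fingerprint: str
    config: ProfileConfig

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# cardioprofile {__version__} profile table\n")
            fh.write(f"# fingerprint: {self.fingerprint}\n")
            fh.write("# units: cl ms, apd90 ms, delta_apd_pct percent, "
                     "delta_apd ms\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def row(self, drug: str, cell: str, cl: float) -> pd.Series:
        m = self.df[(self.df.drug == drug) & (self.df.cell == cell)
                    & (self.df.cl == cl)]
        if m.empty:
            raise KeyError(f"no row for ({drug}, {cell}, {cl})")
        return m.iloc[0]


def _fingerprint(config: ProfileConfig, cells: Sequence[str],
                 drugs: Sequence[str], cl_grid: Sequence[float],
                 param_checksums: dict[str, str]) -> str:
    payload = json.dumps({
        "version": __version__,
        "config": asdict(config),
        "cells": list(cells),
        "drugs": list(drugs),
        "cl_grid": [float(c) for c in cl_grid],
        "params": param_checksums,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _ead_window_charges(trace: BeatTrace, ead_time: float,
                        candidates: Sequence[str]) -> dict[str, float] | None:
    """Inward charge carried by each candidate current over one EAD upstroke
    (local V minimum to the following local maximum); None if degenerate."""
    t = np.asarray(trace.t)
    v = np.asarray(trace.v)
    i_ead = int(np.argmin(np.abs(t - ead_time)))
    dv = np.diff(v[i_ead:])
    turn = np.nonzero(dv < 0)[0]
    rise_start = i_ead
    # skip any residual descent right at the marker
    pos = np.nonzero(dv > 0)[0]
    if pos.size:
        rise_start = i_ead + pos[0]
        dv = np.diff(v[rise_start:])
        turn = np.nonzero(dv < 0)[0]
    i_top = rise_start + (turn[0] if turn.size else len(dv))
    if i_top - rise_start < 2:
        return None
    dt = t[1] - t[0]
    out = {}
    for name in candidates:
        if name not in trace.current_names:
            continue
        cur = trace.current(name)[rise_start:i_top + 1]
        out[name] = -float(np.trapezoid(np.minimum(cur, 0.0), dx=dt))
    return out


def attribute_ead_current(trace: BeatTrace, ead_time: float,
                          candidates: Sequence[str] = ("I_NaL", "I_CaL")) -> str:
    """Name the dominant depolarizing current of one EAD.

    Over the window from the EAD's local voltage minimum to the following
    local maximum, each candidate current's inward (negative) portion is
    integrated; the candidate carrying the largest inward charge wins.
    Returns ``"undetermined"`` when the window is degenerate (< 2 samples).
    """
    charges = _ead_window_charges(trace, ead_time, candidates)
    if not charges:
        return "undetermined"
    best = max(charges, key=charges.get)
    return best if charges[best] > 0.0 else "undetermined"


def _effective_apd90(beats: Sequence[BeatTrace]) -> float:
    """APD90 measured across beat boundaries.

    In heavy EAD regimes a prolonged beat may repolarize only during the
    following cycle; its duration is then measured on the concatenated trace,
    anchored at the strongest upstroke among the kept beats.
    """
    from .biomarkers import apd_from_arrays

    tail = beats[-4:]
    if not tail:
        return float("nan")
    best, best_dvdt = 0, -np.inf
    for i, tr in enumerate(tail):
        d = float(np.max(np.diff(tr.v)))
        if d > best_dvdt:
            best, best_dvdt = i, d
    t_parts, v_parts, offset = [], [], 0.0
    for tr in tail[best:]:
        t_parts.append(tr.t[:-1] + offset)
        v_parts.append(tr.v[:-1])
        offset += tr.cl
    t = np.concatenate(t_parts)
    v = np.concatenate(v_parts)
    try:
        a = apd_from_arrays(t, v, 0.9)
    except ValueError:
        return float("nan")
    from .biomarkers import RepolarizationFailure
    if isinstance(a, RepolarizationFailure):
        return float("nan")
    return float(a)


def _profile_one(result: PacingResult, control: PacingResult,
                 config: ProfileConfig) -> dict:
    """Biomarkers of one (drug, cell, CL) combination vs its control."""
    row: dict = {
        "status": "ok",
        "converged": result.converged,
        "n_beats": result.n_beats,
    }
    if result.repolarization_failure:
        row["status"] = "repolarization_failure"

    apd_ctrl = control.apd90
    apd_drug = result.apd90
    if np.any(~np.isfinite(result.apd90_series[-2:])):
        # a beat spilled past its cycle: measure across beat boundaries
        apd_drug = _effective_apd90(result.beats)
    row["apd90_control"] = apd_ctrl
    row["apd90_drug"] = apd_drug
    if np.isfinite(apd_ctrl) and np.isfinite(apd_drug):
        row["delta_apd_pct"] = delta_apd_percent(apd_drug, apd_ctrl)
    else:
        row["delta_apd_pct"] = float("nan")

    # steady-state beats = the kept tail (alternans window)
    tail = result.beats[-config.ss_window:]
    ead_counts = []
    charges: dict[str, float] = {}
    for tr in tail:
        n, times = detect_eads(tr, config.theta_rise, config.v_gate)
        ead_counts.append(n)
        for t_e in times:
            q = _ead_window_charges(tr, t_e, config.candidate_currents)
            for name, val in (q or {}).items():
                charges[name] = charges.get(name, 0.0) + val
    row["ead_flag"] = bool(any(ead_counts))
    row["ead_count"] = int(max(ead_counts) if ead_counts else 0)

    if charges and max(charges.values()) > 0.0:
        # dominant depolarizing current: largest inward charge summed over
        # every detected EAD upstroke in the steady-state window
        row["dominant_ead_current"] = max(charges, key=charges.get)
    else:
        row["dominant_ead_current"] = None

    if len(result.apd90_series) >= 8:
        rep = detect_alternans(result.apd90_series, result.ead_counts,
                               config.theta_alt, min(10, len(result.apd90_series)))
        row["alternans_flag"] = bool(rep.is_alternans) if rep.valid else False
        row["delta_apd"] = rep.delta_apd
        row["alternans_pattern"] = rep.pattern
    else:
        row["alternans_flag"] = False
        row["delta_apd"] = float("nan")
        row["alternans_pattern"] = None
    return row


def run_profile(drugs: Sequence[DrugSpec],
                cell_types: Sequence[CellType | str] = tuple(CellType),
                cl_grid: Sequence[float] = DEFAULT_CL_GRID,
                config: ProfileConfig | None = None,
                model_name: str | None = None) -> ProfileTable:
    """Profile every (drug, cell type, cycle length) combination.

    Controls are paced once per (cell, CL) and shared across drugs.  Every
    requested combination appears in the table, possibly with a failure
    status.
    """
    config = config or ProfileConfig()
    controller = config.controller()
    cells = [ct if isinstance(ct, CellType) else CellType.parse(ct)
             for ct in cell_types]

    rows: list[dict] = []
    checksums: dict[str, str] = {}
    for cell in cells:
        params, state = make_cell(cell)
        model = get_model(model_name or params.model_name)
        checksums[cell.value] = params.checksum()
        for cl in cl_grid:
            try:
                control = pace(model, params, config.protocol(cl), controller,
                               initial_state=state,
                               keep_beats=config.keep_beats)
            except IntegrationFailure as err:
                logger.warning("control %s CL=%g failed: %s", cell.value, cl, err)
                control = None
            for drug in drugs:
                base = {"drug": drug.name, "cell": cell.value, "cl": float(cl)}
                if control is None:
                    rows.append({**base, "status": "control_failed"})
                    continue
                try:
                    dparams = apply_drug(params, drug,
                                         drug.eftpc * config.conc_scale)
                    # the drug is applied to the cell beating at its
                    # drug-free steady state for this CL
                    result = pace(model, dparams, config.protocol(cl),
                                  controller,
                                  initial_state=control.final_state,
                                  keep_beats=config.keep_beats)
                    rows.append({**base,
                                 **_profile_one(result, control, config)})
                except IntegrationFailure as err:
                    logger.warning("%s %s CL=%g failed: %s",
                                   drug.name, cell.value, cl, err)
                    rows.append({**base, "status": "integration_failure"})

    df = pd.DataFrame(rows)
    fp = _fingerprint(config, [c.value for c in cells],
                      [d.name for d in drugs], cl_grid, checksums)
    return ProfileTable(df=df, fingerprint=fp, config=config)


def adaptation_curve(table: ProfileTable, drug: str,
                     cell: CellType | str) -> RateAdaptationCurve:
    """Rate-adaptation curve (CL -> APD90/EAD/alternans) for one drug x cell."""
    cell_label = cell.value if isinstance(cell, CellType) else cell
    curve = RateAdaptationCurve()
    sub = table.df[(table.df.drug == drug) & (table.df.cell == cell_label)]
    for _, r in sub.iterrows():
        if r.get("status") not in ("ok", "repolarization_failure"):
            continue
        curve.add(r["cl"], r.get("apd90_drug", float("nan")),
                  bool(r.get("ead_flag", False)),
                  bool(r.get("alternans_flag", False)))
    return curve


def rank_vulnerability(table: ProfileTable) -> pd.DataFrame:
    """Per-cell-type vulnerability summary: number of EAD-positive drugs and
    the maximum delta-APD% across the grid.

    An incomplete table yields a partial summary with a coverage column.
    """
    df = table.df
    if df.empty:
        return pd.DataFrame(
            columns=["cell", "ead_drug_count", "max_delta_apd_pct", "coverage"])
    out = []
    for cell, sub in df.groupby("cell", sort=False):
        ok = sub[sub.status.isin(["ok", "repolarization_failure"])] \
            if "status" in sub else sub
        ead_drugs = 0
        if "ead_flag" in ok and not ok.empty:
            ead_drugs = ok[ok.ead_flag.eq(True)].drug.nunique()
        max_delta = float("nan")
        if "delta_apd_pct" in ok and ok.delta_apd_pct.notna().any():
            max_delta = float(ok.delta_apd_pct.max())
        out.append({
            "cell": cell,
            "ead_drug_count": int(ead_drugs),
            "max_delta_apd_pct": max_delta,
            "coverage": len(ok) / len(sub) if len(sub) else 0.0,
        })
    return pd.DataFrame(out)
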