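"""Time integration of the fusion-fission/ATP ODE system.

Single-scenario integration (:func:`integrate`), the full ten-scenario panel
of five HGSC phenotypes under serum-fed (+S) and serum-starved (SS)
conditions (:func:`run_panel`), and loading of the packaged ultrastructure
preset table (:func:`load_presets`).

The packaged preset table stores, per cell line and condition, the
normalized cristae width/count, crista-junction width, membrane potential
and the OPA1/DRP1 levels.  One cell of the OVCAR3-SS row (``m_p``) is absent
from the source measurements; the loader refuses to build that scenario
unless the documented fill rule — reuse the same cell line's +S value — is
explicitly enabled (``fill_missing="plus_serum"``), so that no parameter is
ever invented silently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DivergenceError, SchemaError
from .model import (
    PLUS_SERUM,
    SERUM_STARVED,
    DynamicsConstants,
    ScenarioParams,
    StructuralParams,
    SystemState,
    _derivative,
    atp_production_factor,
    fission_rate,
    fusion_rate,
)

__all__ = [
    "SolverSettings",
    "Trajectory",
    "integrate",
    "run_panel",
    "load_presets",
    "packaged_presets_path",
    "CONDITION_LABELS",
    "CONDITION_FROM_LABEL",
    "DEFAULT_STRESS",
]

logger = logging.getLogger(__name__)

#: condition identifier -> label used in the CSV dialect
CONDITION_LABELS = {PLUS_SERUM: "+S", SERUM_STARVED: "SS"}
CONDITION_FROM_LABEL = {v: k for k, v in CONDITION_LABELS.items()}

#: Default stress level per condition.  +S is the stress-free reference
#: (e^0 = 1 leaves fusion and fission unscaled).  The SS value is calibrated
#: so that starvation biases the system far enough toward fusion to deplete
#: the unfused classes, the regime the model is meant to describe; see
#: docs/methods.md for the derivation.
DEFAULT_STRESS = {PLUS_SERUM: 0.0, SERUM_STARVED: 2.5}

PRESET_COLUMNS = ["cell_line", "condition", "c_w", "c_n", "c_jw", "m_p", "opa1", "drp1"]


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings.

    ``method`` selects scipy's adaptive RK45 (``adaptive_rk``) or the
    in-package fixed-step classical RK4 / forward Euler steppers.  Population
    counts that dip marginally below zero are integration artifacts at these
    magnitudes; ``negativity_policy="clip_warn"`` clips them to zero in the
    stored trajectory with a logged warning (``"error"`` raises instead).
    The ATP pool is floored at zero analogously (``atp_floor_policy``).
    Any state component exceeding ``blowup_cap`` aborts with a
    :class:`~mitodyn.errors.DivergenceError`.
    """

    t_start: float = 0.0
    t_end: float = 10.0
    method: Literal["adaptive_rk", "fixed_rk4", "fixed_euler"] = "adaptive_rk"
    rtol: float = 1e-9
    atol: float = 1e-12
    dt: float = 1e-3
    n_out: int = 501
    negativity_policy: Literal["clip_warn", "error"] = "clip_warn"
    atp_floor_policy: Literal["floor_zero_warn", "allow"] = "floor_zero_warn"
    blowup_cap: float = 1e12

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError(f"t_end ({self.t_end}) must be >= t_start ({self.t_start})")
        if self.rtol <= 0 or self.atol <= 0 or self.dt <= 0:
            raise ValueError("tolerances and step size must be > 0")
        if self.n_out < 1:
            raise ValueError("n_out must be >= 1")


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered solution of the ODE system with full provenance."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 5): n_hu, n_du, n_hf, n_df, atp
    scenario: ScenarioParams
    settings: SolverSettings
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states lengths differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def index_at(self, t: float) -> int:
        """Index of the stored sample nearest to ``t`` (``t`` must lie in the
        trajectory span)."""
        t0, t1 = self.times[0], self.times[-1]
        if not (t0 - 1e-9 <= t <= t1 + 1e-9):
            raise ValueError(f"t={t} outside trajectory span [{t0}, {t1}]")
        return int(np.argmin(np.abs(self.times - t)))

    def state_at(self, t: float) -> SystemState:
        return SystemState.from_array(self.states[self.index_at(t)])

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(self.states[-1])

    @property
    def totals(self) -> np.ndarray:
        """Total mitochondrial number at each stored time."""
        return self.states[:, :4].sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_hu": self.states[:, 0],
                "n_du": self.states[:, 1],
                "n_hf": self.states[:, 2],
                "n_df": self.states[:, 3],
                "atp": self.states[:, 4],
            }
        )


def _apply_policies(times, states, settings: SolverSettings, scenario) -> tuple[np.ndarray, tuple[str, ...]]:
    """Enforce negativity/ATP-floor policies on the raw solver output."""
    notes: list[str] = []
    states = np.array(states, dtype=float)
    pops = states[:, :4]
    if (pops < 0).any():
        worst = float(pops.min())
        msg = (
            f"{scenario.cell_line}/{scenario.condition}: population excursion to "
            f"{worst:.3e} clipped to 0 (negativity_policy={settings.negativity_policy})"
        )
        if settings.negativity_policy == "error":
            raise DivergenceError(msg, float(times[int(np.argwhere(pops < 0)[0][0])]))
        np.clip(pops, 0.0, None, out=pops)
        logger.warning(msg)
        notes.append(msg)
    atp = states[:, 4]
    if (atp < 0).any():
        worst = float(atp.min())
        msg = (
            f"{scenario.cell_line}/{scenario.condition}: ATP excursion to "
            f"{worst:.3e} floored at 0 (atp_floor_policy={settings.atp_floor_policy})"
        )
        if settings.atp_floor_policy == "floor_zero_warn":
            np.clip(atp, 0.0, None, out=atp)
            logger.warning(msg)
            notes.append(msg)
    return states, tuple(notes)


def integrate(
    scenario: ScenarioParams,
    initial: SystemState | None = None,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate one scenario over ``[t_start, t_end]``.

    ``initial`` defaults to the reference initial conditions (one
    mitochondrion per class, zero ATP).  Returns a :class:`Trajectory`
    sampled on ``n_out`` equispaced times (adaptive method) or at a stride of
    the fixed step.

    Raises
    ------
    DivergenceError
        If any state component exceeds ``settings.blowup_cap`` (possible in
        constant-biogenesis mode, where net growth is unbounded), carrying
        the last valid time.
    """
    initial = initial if initial is not None else SystemState.initial()
    settings = settings if settings is not None else SolverSettings()

    theta = atp_production_factor(scenario.structural)
    F = fusion_rate(scenario.constants.F_0, scenario.opa1)
    K = fission_rate(scenario.constants.K_0, scenario.drp1)
    constants = scenario.constants

    y0 = initial.to_array()
    t0, t1 = settings.t_start, settings.t_end
    if t1 == t0:
        return Trajectory(np.array([t0]), y0[None, :].copy(), scenario, settings)

    def rhs(t, y):
        return _derivative(y, theta, F, K, constants)

    if settings.method == "adaptive_rk":
        cap = settings.blowup_cap

        def blowup(t, y):
            return cap - np.max(np.abs(y))

        blowup.terminal = True  # type: ignore[attr-defined]
        t_eval = np.linspace(t0, t1, settings.n_out)
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="RK45", rtol=settings.rtol,
            atol=settings.atol, t_eval=t_eval, events=blowup,
        )
        if sol.status == 1:  # blow-up event fired
            last = float(sol.t_events[0][0]) if len(sol.t_events[0]) else t0
            raise DivergenceError(
                f"{scenario.cell_line}/{scenario.condition}: state exceeded "
                f"magnitude cap {cap:g} at t={last:.6g}",
                last_valid_time=last,
            )
        if not sol.success:
            raise DivergenceError(
                f"{scenario.cell_line}/{scenario.condition}: solver failed: {sol.message}",
                last_valid_time=float(sol.t[-1]) if len(sol.t) else t0,
            )
        times, states = sol.t, sol.y.T
    else:
        times, states = _fixed_step(rhs, y0, t0, t1, settings, scenario)

    states, notes = _apply_policies(times, states, settings, scenario)
    return Trajectory(np.asarray(times), states, scenario, settings, notes)


def _fixed_step(rhs, y0, t0, t1, settings: SolverSettings, scenario):
    """Fixed-step forward Euler or classical RK4 with stride-thinned output."""
    dt = settings.dt
    n_steps = max(1, int(round((t1 - t0) / dt)))
    dt = (t1 - t0) / n_steps  # snap so the last step lands exactly on t1
    stride = max(1, n_steps // max(1, settings.n_out - 1))
    cap = settings.blowup_cap

    y = np.array(y0, dtype=float)
    times = [t0]
    states = [y.copy()]
    rk4 = settings.method == "fixed_rk4"
    for i in range(n_steps):
        t = t0 + i * dt
        if rk4:
            k1 = rhs(t, y)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2)
            k4 = rhs(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            y = y + dt * rhs(t, y)
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > cap:
            raise DivergenceError(
                f"{scenario.cell_line}/{scenario.condition}: state exceeded "
                f"magnitude cap {cap:g} at t={t + dt:.6g}",
                last_valid_time=t,
            )
        if (i + 1) % stride == 0 or i == n_steps - 1:
            times.append(t0 + (i + 1) * dt)
            states.append(y.copy())
    return np.array(times), np.array(states)


def packaged_presets_path():
    """Filesystem path of the packaged ultrastructure preset table."""
    return resources.files("mitodyn.data") / "table1_presets.csv"


def load_presets(
    path=None,
    *,
    fill_missing: Literal["plus_serum"] | None = None,
    constants: DynamicsConstants | None = None,
    stress: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], ScenarioParams]:
    """Load a preset table into validated scenarios.

    Parameters
    ----------
    path
        CSV with header ``cell_line,condition,c_w,c_n,c_jw,m_p,opa1,drp1``
        and condition spelled ``+S`` or ``SS``.  Defaults to the packaged
        table.
    fill_missing
        ``None`` (default): a row with an empty numeric cell is rejected
        with a :class:`~mitodyn.errors.SchemaError`.  ``"plus_serum"``: an
        empty cell in an SS row is filled from the same cell line's +S row,
        with a logged warning (the documented fill rule for the packaged
        OVCAR3-SS row, whose membrane potential is not printed).
    constants
        Template :class:`DynamicsConstants` applied to every scenario; its
        ``stress`` field is overridden per condition.
    stress
        Mapping from condition (``plus_serum``/``serum_starved``) to stress
        level; defaults to :data:`DEFAULT_STRESS`.

    Returns
    -------
    dict
        ``(cell_line, condition)`` → :class:`ScenarioParams`, with condition
        as ``"plus_serum"`` / ``"serum_starved"``.
    """
    if path is None:
        path = packaged_presets_path()
    constants = constants if constants is not None else DynamicsConstants()
    stress_map = dict(DEFAULT_STRESS)
    if stress is not None:
        stress_map.update(stress)

    try:
        df = pd.read_csv(path, encoding="utf-8-sig", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty preset file") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing_cols = [c for c in PRESET_COLUMNS if c not in df.columns]
    extra_cols = [c for c in df.columns if c not in PRESET_COLUMNS]
    if missing_cols or extra_cols:
        raise SchemaError(
            f"{path}: preset schema mismatch; missing columns {missing_cols}, "
            f"unexpected columns {extra_cols}"
        )
    if df.empty:
        raise SchemaError(f"{path}: preset file has no data rows")

    numeric_cols = PRESET_COLUMNS[2:]
    bad_rows: list[str] = []
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    plus_rows = {
        str(r.cell_line): r for r in df.itertuples() if str(r.condition) == "+S"
    }

    presets: dict[tuple[str, str], ScenarioParams] = {}
    for r in df.itertuples():
        cell = str(r.cell_line)
        label = str(r.condition)
        if label not in CONDITION_FROM_LABEL:
            bad_rows.append(f"row {r.Index}: unknown condition {label!r} (expected '+S' or 'SS')")
            continue
        cond = CONDITION_FROM_LABEL[label]
        values = {col: getattr(r, col) for col in numeric_cols}
        nan_cols = [col for col, v in values.items() if not math.isfinite(v)]
        if nan_cols:
            if fill_missing == "plus_serum" and label == "SS" and cell in plus_rows:
                fill_failed = False
                for col in nan_cols:
                    fill = getattr(plus_rows[cell], col)
                    if not math.isfinite(fill):
                        bad_rows.append(
                            f"row {r.Index} ({cell} {label}): cannot fill {col}; +S value also missing"
                        )
                        fill_failed = True
                        break
                    logger.warning(
                        "%s %s: missing %s filled from +S row (value %s)", cell, label, col, fill
                    )
                    values[col] = float(fill)
                if fill_failed:
                    continue
            else:
                bad_rows.append(
                    f"row {r.Index} ({cell} {label}): missing/non-numeric value(s) in {nan_cols} "
                    "(enable the documented fill rule to reuse the +S value)"
                )
                continue
        out_of_range = [c for c in numeric_cols if values[c] < 0]
        if out_of_range:
            bad_rows.append(f"row {r.Index} ({cell} {label}): negative value(s) in {out_of_range}")
            continue
        key = (cell, cond)
        if key in presets:
            bad_rows.append(f"row {r.Index}: duplicate scenario {cell} {label}")
            continue
        presets[key] = ScenarioParams(
            cell_line=cell,
            condition=cond,
            structural=StructuralParams(
                c_w=values["c_w"], c_n=values["c_n"], c_jw=values["c_jw"], m_p=values["m_p"]
            ),
            opa1=values["opa1"],
            drp1=values["drp1"],
            constants=replace(constants, stress=stress_map[cond]),
        )
    if bad_rows:
        raise SchemaError(f"{path}: invalid preset rows:\n  " + "\n  ".join(bad_rows))
    return presets


def run_panel(
    presets: Mapping[tuple[str, str], ScenarioParams],
    settings: SolverSettings | None = None,
    *,
    require: Iterable[tuple[str, str]] | None = None,
    initial: SystemState | None = None,
) -> dict[tuple[str, str], Trajectory]:
    """Integrate every scenario in ``presets`` with identical settings.

    ``require`` optionally names the scenarios that must be present; a
    missing one raises ``KeyError`` naming the (cell_line, condition) pair.
    The result is deterministic given settings.
    """
    if require is not None:
        missing = [k for k in require if k not in presets]
        if missing:
            raise KeyError(f"presets missing required scenarios: {missing}")
    return {key: integrate(sc, initial=initial, settings=settings) for key, sc in sorted(presets.items())}
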