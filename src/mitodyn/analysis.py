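"""Qualitative readouts of the simulated panel.

The model's free constants (α, ε, M_H, M_D, F_0, K_0, stress) are not fixed
by any measurement, so the qualitative statements read off the panel — which
class dominates, whether unfused mitochondria are depleted under starvation,
how phenotypes rank in fused counts or ATP, and whether starvation raises
ATP — are implemented as *reported diagnostics* with explicit pass/fail
flags, plus a parameter sweep to quantify how robust each claim is across
the free-constant space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DivergenceError
from .model import CELL_LINES, PLUS_SERUM, SERUM_STARVED, ScenarioParams
from .simulate import SolverSettings, Trajectory, integrate

__all__ = [
    "PanelSummary",
    "AtpContrast",
    "summarize_panel",
    "unfused_depletion",
    "atp_contrast",
    "rank_phenotypes",
    "sweep_constants",
]

#: Dynamics-constant names accepted by :func:`sweep_constants` grids.
SWEEPABLE = ("alpha", "epsilon", "M_H", "M_D", "F_0", "K_0", "stress", "mu")


@dataclass(frozen=True)
class PanelSummary:
    """Terminal states and derived metrics of a panel run.

    ``metrics`` has one row per (cell_line, condition) with columns
    ``n_hu, n_du, n_hf, n_df, atp, total, unfused_fraction, fused_fraction``
    evaluated at the sample nearest ``t``.  ``fractions`` maps each scenario
    to its full class-fraction time series (columns ``time, f_hu, f_du,
    f_hf, f_df``; fractions sum to 1 wherever the total is positive).
    """

    metrics: pd.DataFrame
    fractions: dict[tuple[str, str], pd.DataFrame]
    t: float


def summarize_panel(panel: Mapping[tuple[str, str], Trajectory], t: float | None = None) -> PanelSummary:
    """Summarize every trajectory of a panel at time ``t`` (default: each
    trajectory's final time)."""
    rows = []
    fractions: dict[tuple[str, str], pd.DataFrame] = {}
    t_used = None
    for key, traj in sorted(panel.items()):
        tt = traj.times[-1] if t is None else t
        t_used = float(tt)
        s = traj.state_at(tt)
        rows.append(
            {
                "cell_line": key[0],
                "condition": key[1],
                "n_hu": s.n_hu,
                "n_du": s.n_du,
                "n_hf": s.n_hf,
                "n_df": s.n_df,
                "atp": s.atp,
                "total": s.total,
                "unfused_fraction": s.unfused_fraction,
                "fused_fraction": 1.0 - s.unfused_fraction if s.total > 0 else 0.0,
            }
        )
        tot = traj.totals
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = np.where(tot[:, None] > 0, traj.states[:, :4] / tot[:, None], 0.0)
        fractions[key] = pd.DataFrame(
            {"time": traj.times, "f_hu": fr[:, 0], "f_du": fr[:, 1], "f_hf": fr[:, 2], "f_df": fr[:, 3]}
        )
    metrics = pd.DataFrame(rows).set_index(["cell_line", "condition"])
    return PanelSummary(metrics=metrics, fractions=fractions, t=t_used if t_used is not None else 0.0)


def unfused_depletion(trajectory: Trajectory, t: float) -> float:
    """Unfused fraction (HU+DU)/total at the stored sample nearest ``t``.

    Under starvation the model predicts this falls toward zero as fusion
    outpaces fission.  Returns 0 for an empty system; raises ``ValueError``
    if ``t`` lies outside the trajectory span.
    """
    return trajectory.state_at(t).unfused_fraction


@dataclass(frozen=True)
class AtpContrast:
    """Signed SS−(+S) ATP difference and their ratio at one time point.
    ``ratio`` is ``nan`` (and ``ratio_defined`` False) when the +S ATP is 0."""

    difference: float
    ratio: float
    ratio_defined: bool


def atp_contrast(traj_ss: Trajectory, traj_s: Trajectory, t: float) -> AtpContrast:
    """Compare ATP at time ``t`` between the SS and +S trajectories of the
    same cell line."""
    if traj_ss.scenario.cell_line != traj_s.scenario.cell_line:
        raise ContractError(
            f"atp_contrast requires trajectories of the same cell line, got "
            f"{traj_ss.scenario.cell_line!r} and {traj_s.scenario.cell_line!r}"
        )
    a_ss = traj_ss.state_at(t).atp
    a_s = traj_s.state_at(t).atp
    if a_s == 0:
        return AtpContrast(a_ss - a_s, float("nan"), False)
    return AtpContrast(a_ss - a_s, a_ss / a_s, True)


def rank_phenotypes(
    panel: Mapping[tuple[str, str], Trajectory],
    metric: str,
    condition: str,
    t: float,
    cell_lines: Sequence[str] = CELL_LINES,
) -> list[str]:
    """Cell lines in descending order of ``metric`` (``"hf_count"`` or
    ``"atp"``) at time ``t`` under ``condition``; ties broken
    lexicographically by cell-line identifier."""
    if metric not in ("hf_count", "atp"):
        raise ValueError(f"metric must be 'hf_count' or 'atp', got {metric!r}")
    missing = [(cl, condition) for cl in cell_lines if (cl, condition) not in panel]
    if missing:
        raise ContractError(f"panel missing scenarios: {missing}")
    values = {}
    for cl in cell_lines:
        s = panel[(cl, condition)].state_at(t)
        values[cl] = s.n_hf if metric == "hf_count" else s.atp
    return sorted(values, key=lambda cl: (-values[cl], cl))


def sweep_constants(
    base: ScenarioParams,
    grid: Mapping[str, Sequence[float]],
    settings: SolverSettings | None = None,
    *,
    plus_serum_counterpart: ScenarioParams | None = None,
) -> pd.DataFrame:
    """Evaluate panel metrics over a grid of free-constant values.

    ``grid`` maps constant names (subset of ``alpha, epsilon, M_H, M_D, F_0,
    K_0, stress, mu``) to value sequences; the Cartesian product is run.
    Each row reports the terminal unfused fraction, HF count and ATP for
    ``base`` with those overrides, a ``fused_dominant`` flag (fused fraction
    > 0.5 at t_end), and — when ``plus_serum_counterpart`` is given — the
    terminal ATP of the counterpart under the same overrides (``stress``
    excepted, which only applies to ``base``) and an ``atp_ss_gt_plus_s``
    flag.  Divergent grid points are recorded per-row (``diverged=True``,
    NaN metrics), not raised.
    """
    settings = settings if settings is not None else SolverSettings()
    names = list(grid)
    unknown = [n for n in names if n not in SWEEPABLE]
    if unknown:
        raise ValueError(f"cannot sweep {unknown}; sweepable constants are {SWEEPABLE}")
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        overrides = dict(zip(names, combo))
        row: dict = dict(overrides)
        try:
            traj = integrate(base.with_constants(**overrides), settings=settings)
            end = traj.final_state
            row.update(
                unfused_fraction=end.unfused_fraction,
                hf_count=end.n_hf,
                atp=end.atp,
                fused_dominant=(1.0 - end.unfused_fraction) > 0.5,
                diverged=False,
            )
        except DivergenceError as exc:
            row.update(
                unfused_fraction=np.nan, hf_count=np.nan, atp=np.nan,
                fused_dominant=False, diverged=True,
                last_valid_time=exc.last_valid_time,
            )
            rows.append(row)
            continue
        if plus_serum_counterpart is not None:
            cp_overrides = {k: v for k, v in overrides.items() if k != "stress"}
            try:
                cp = integrate(
                    plus_serum_counterpart.with_constants(**cp_overrides), settings=settings
                )
                row["atp_plus_s"] = cp.final_state.atp
                row["atp_ss_gt_plus_s"] = row["atp"] > row["atp_plus_s"]
            except DivergenceError:
                row["atp_plus_s"] = np.nan
                row["atp_ss_gt_plus_s"] = False
        rows.append(row)
    return pd.DataFrame(rows)
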