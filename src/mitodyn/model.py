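"""Kinetic model of mitochondrial fusion-fission dynamics and ATP energetics.

The model tracks four mitochondrial classes — healthy unfused (HU), deviant
unfused (DU), healthy fused (HF) and deviant fused (DF) — together with a
cell-level ATP pool.  Fusion converts unfused mitochondria to the matching
fused class at rate ``F·[ATP]·e^stress`` and fission converts them back at
``K·[ATP]·e^(−stress)``; nutritional stress therefore biases the system
toward the fused state.  Only unfused mitochondria are cleared by mitophagy
(rates ``M_H``, ``M_D``), and biogenesis ``B`` replenishes all four classes
uniformly — by default at exactly the total mitophagy flux, so the total
mitochondrial number is conserved.

ATP is produced by every mitochondrion at a rate proportional to the
ultrastructural factor

    θ = (c_n + e^{m_p}) / (c_w + c_jw)

(cristae count per unit length ``c_n``, membrane potential ``m_p``, cristae
width ``c_w``, crista-junction width ``c_jw``): more, thinner cristae with
tight junctions and high membrane potential mean more efficient OXPHOS.
Healthy mitochondria out-produce deviant ones by a factor α ≥ 1 and fused
ones out-produce unfused by ε ≥ 1.  ATP is consumed by a constant cellular
demand μ and by the fusion/fission machinery itself.

The five coupled ODEs implemented by :func:`state_derivative` are

    dN_HU/dt = (B − M_H − F·A·e^s)·N_HU + K·A·e^{−s}·N_HF
    dN_DU/dt = (B − M_D − F·A·e^s)·N_DU + K·A·e^{−s}·N_DF
    dN_HF/dt = (B − K·A·e^{−s})·N_HF + F·A·e^s·N_HU
    dN_DF/dt = (B − K·A·e^{−s})·N_DF + F·A·e^s·N_DU
    dA/dt    = θ·[ε·(α·N_HF + N_DF) + (α·N_HU + N_DU)] − μ
               − K·A·(N_HF+N_DF)·e^{−s} − F·A·(N_HU+N_DU)·e^s

with A = [ATP] and s = stress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "PLUS_SERUM",
    "SERUM_STARVED",
    "CELL_LINES",
    "StructuralParams",
    "DynamicsConstants",
    "ScenarioParams",
    "SystemState",
    "atp_production_factor",
    "fusion_rate",
    "fission_rate",
    "biogenesis_rate",
    "state_derivative",
]

PLUS_SERUM = "plus_serum"
SERUM_STARVED = "serum_starved"
Condition = Literal["plus_serum", "serum_starved"]

#: The five HGSC cell lines, ordered along the epithelial→mesenchymal gradient
#: (E, iE, E/M, iM, M).
CELL_LINES = ("OVCAR3", "CAOV3", "OVCA420", "A4", "OVMZ6")


@dataclass(frozen=True)
class StructuralParams:
    """Normalized mitochondrial ultrastructure parameters of one scenario.

    Parameters
    ----------
    c_w
        Average cristae width (normalized, dimensionless).
    c_n
        Number of cristae per unit mitochondrial length (normalized).
    c_jw
        Crista-junction width (normalized).
    m_p
        Mitochondrial (trans)membrane potential, normalized; enters the ATP
        production factor through ``e^{m_p}``.
    """

    c_w: float
    c_n: float
    c_jw: float
    m_p: float

    def __post_init__(self) -> None:
        for name in ("c_w", "c_n", "c_jw", "m_p"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"StructuralParams.{name} must be finite and >= 0, got {v}")
        if self.c_w + self.c_jw <= 0:
            raise ValueError(
                "StructuralParams requires c_w + c_jw > 0 "
                "(denominator of the ATP production factor)"
            )


@dataclass(frozen=True)
class DynamicsConstants:
    """Free rate constants and efficiency factors of the kinetic model.

    These are not fixed by ultrastructure measurements; the defaults define
    the package's reference parameterization (see docs/methods.md).

    Parameters
    ----------
    F_0, K_0
        Base fusion and fission rates (per time per ATP unit); scaled by the
        measured OPA1 and DRP1 levels respectively.
    M_H, M_D
        Mitophagy rates of healthy and deviant *unfused* mitochondria
        (per time).  Deviant mitochondria are cleared faster by default.
    alpha
        Healthy-over-deviant ATP production efficiency, ≥ 1.
    epsilon
        Fused-over-unfused ATP production efficiency, ≥ 1.
    mu
        Constant cellular ATP consumption (ATP units per time).
    stress
        Nutritional stress level; multiplies fusion by ``e^stress`` and
        fission by ``e^(−stress)``.  0 models the serum-fed (+S) condition.
    biogenesis_mode
        ``"balance"`` recomputes biogenesis at every instant to exactly
        offset mitophagy (conserving total mitochondrial number);
        ``"constant"`` uses the fixed rate ``B_const``.
    B_const
        Biogenesis rate in ``"constant"`` mode (per time).
    """

    F_0: float = 1.0
    K_0: float = 1.0
    M_H: float = 0.1
    M_D: float = 0.5
    alpha: float = 2.0
    epsilon: float = 2.0
    mu: float = 3.0
    stress: float = 0.0
    biogenesis_mode: Literal["balance", "constant"] = "balance"
    B_const: float = 0.0

    def __post_init__(self) -> None:
        for name in ("F_0", "K_0", "M_H", "M_D", "mu", "B_const", "stress"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"DynamicsConstants.{name} must be finite and >= 0, got {v}")
        if self.alpha < 1:
            raise ValueError(f"alpha must be >= 1 (healthy at least as efficient), got {self.alpha}")
        if self.epsilon < 1:
            raise ValueError(f"epsilon must be >= 1 (fused at least as efficient), got {self.epsilon}")
        if self.biogenesis_mode not in ("balance", "constant"):
            raise ValueError(f"unknown biogenesis_mode {self.biogenesis_mode!r}")


@dataclass(frozen=True)
class ScenarioParams:
    """One phenotype × condition cell of the ultrastructure table plus the
    free model constants — everything needed to evaluate the ODE right-hand
    side."""

    cell_line: str
    condition: Condition
    structural: StructuralParams
    opa1: float
    drp1: float
    constants: DynamicsConstants = field(default_factory=DynamicsConstants)

    def __post_init__(self) -> None:
        if self.condition not in (PLUS_SERUM, SERUM_STARVED):
            raise ValueError(f"condition must be {PLUS_SERUM!r} or {SERUM_STARVED!r}, got {self.condition!r}")
        if not math.isfinite(self.opa1) or self.opa1 < 0:
            raise ValueError(f"opa1 must be finite and >= 0, got {self.opa1}")
        if not math.isfinite(self.drp1) or self.drp1 < 0:
            raise ValueError(f"drp1 must be finite and >= 0, got {self.drp1}")

    def with_constants(self, **overrides) -> "ScenarioParams":
        """Return a copy with some dynamics constants replaced."""
        return replace(self, constants=replace(self.constants, **overrides))


@dataclass(frozen=True)
class SystemState:
    """The five dynamical variables at one instant: the four mitochondrial
    class counts and the ATP concentration (model units)."""

    n_hu: float
    n_du: float
    n_hf: float
    n_df: float
    atp: float

    def __post_init__(self) -> None:
        for name in ("n_hu", "n_du", "n_hf", "n_df", "atp"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"SystemState.{name} must be finite and >= 0, got {v}")

    @classmethod
    def initial(cls) -> "SystemState":
        """Reference initial conditions: one mitochondrion per class, no ATP."""
        return cls(1.0, 1.0, 1.0, 1.0, 0.0)

    def to_array(self) -> np.ndarray:
        return np.array([self.n_hu, self.n_du, self.n_hf, self.n_df, self.atp])

    @classmethod
    def from_array(cls, y) -> "SystemState":
        return cls(*(float(v) for v in y))

    @property
    def total(self) -> float:
        """Total mitochondrial number across the four classes."""
        return self.n_hu + self.n_du + self.n_hf + self.n_df

    @property
    def unfused_fraction(self) -> float:
        """(HU + DU) / total; 0 for an empty system."""
        t = self.total
        return (self.n_hu + self.n_du) / t if t > 0 else 0.0


def atp_production_factor(structural: StructuralParams) -> float:
    """ATP production factor θ = (c_n + e^{m_p}) / (c_w + c_jw).

    Strictly increasing in cristae count and membrane potential, strictly
    decreasing in cristae and crista-junction width: more, thinner cristae
    with tight junctions concentrate protons and ATP synthase, boosting
    OXPHOS output.

    Raises
    ------
    DegenerateInputError
        If ``c_w + c_jw`` is zero (guarded again here for raw inputs that
        bypassed :class:`StructuralParams` validation).
    """
    denom = structural.c_w + structural.c_jw
    if denom <= 0:
        raise DegenerateInputError(
            f"ATP production factor undefined: c_w + c_jw = {denom} for {structural}"
        )
    return (structural.c_n + math.exp(structural.m_p)) / denom


def fusion_rate(F_0: float, opa1: float) -> float:
    """Fusion rate F = F_0 · [OPA1]."""
    if F_0 < 0 or opa1 < 0:
        raise ValueError(f"fusion_rate requires F_0 >= 0 and opa1 >= 0, got {F_0}, {opa1}")
    return F_0 * opa1


def fission_rate(K_0: float, drp1: float) -> float:
    """Fission rate K = K_0 · [DRP1]."""
    if K_0 < 0 or drp1 < 0:
        raise ValueError(f"fission_rate requires K_0 >= 0 and drp1 >= 0, got {K_0}, {drp1}")
    return K_0 * drp1


def biogenesis_rate(state: SystemState, constants: DynamicsConstants) -> float:
    """Per-mitochondrion biogenesis rate B.

    In ``"balance"`` mode B satisfies
    ``B·(N_HU+N_HF+N_DU+N_DF) = M_H·N_HU + M_D·N_DU`` exactly, so the number
    of mitochondria created equals the number eliminated through mitophagy;
    defined as 0 for an empty system.  In ``"constant"`` mode returns
    ``B_const``.
    """
    if constants.biogenesis_mode == "constant":
        return constants.B_const
    total = state.total
    if total <= 0:
        return 0.0
    return (constants.M_H * state.n_hu + constants.M_D * state.n_du) / total


def _derivative(y, theta: float, F: float, K: float,
                constants: DynamicsConstants) -> np.ndarray:
    """Right-hand side on a raw 5-vector; single source of the ODE formulas."""
    n_hu, n_du, n_hf, n_df, atp = (float(v) for v in y)
    c = constants
    if c.biogenesis_mode == "constant":
        B = c.B_const
    else:
        total = n_hu + n_du + n_hf + n_df
        B = (c.M_H * n_hu + c.M_D * n_du) / total if total > 0 else 0.0
    e_s = math.exp(c.stress)
    e_ms = math.exp(-c.stress)
    fuse = F * atp * e_s        # per-capita unfused -> fused conversion
    fiss = K * atp * e_ms       # per-capita fused -> unfused conversion
    d_hu = (B - c.M_H - fuse) * n_hu + fiss * n_hf
    d_du = (B - c.M_D - fuse) * n_du + fiss * n_df
    d_hf = (B - fiss) * n_hf + fuse * n_hu
    d_df = (B - fiss) * n_df + fuse * n_du
    d_atp = (
        theta * (c.epsilon * (c.alpha * n_hf + n_df) + (c.alpha * n_hu + n_du))
        - c.mu
        - fiss * (n_hf + n_df)
        - fuse * n_du
        - fuse * n_hu
    )
    return np.array([d_hu, d_du, d_hf, d_df, d_atp])


def state_derivative(state: SystemState, scenario: ScenarioParams) -> np.ndarray:
    """Evaluate the five coupled ODE right-hand sides at ``state``.

    Returns ``[dN_HU, dN_DU, dN_HF, dN_DF, d[ATP]]/dt``.  Fusion and fission
    are one-to-one class conversions (each loss term of an unfused class
    reappears as the gain term of the matching fused class and vice versa)
    and fused classes carry no mitophagy loss.
    """
    theta = atp_production_factor(scenario.structural)
    F = fusion_rate(scenario.constants.F_0, scenario.opa1)
    K = fission_rate(scenario.constants.K_0, scenario.drp1)
    return _derivative(state.to_array(), theta, F, K, scenario.constants)
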