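"""Free-energy model of thermosensing by mixed Tar/Tsr chemoreceptor teams.

The signaling unit is a trimer of receptor dimers sharing a single
active/inactive state.  Each dimer contributes a free-energy difference
(active minus inactive, in units of kBT)

    f_i = f0([L]) + (T - T0) * f1 - [g0 + (T - T0) * g1] * m,

where ``f0`` encodes ligand occupancy, ``T`` is temperature, ``m`` the
methylation level per dimer, and the activity of the team with total free
energy ``F = sum_i f_i`` is the two-state probability ``A = 1 / (1 + e^F)``.

Adaptation is driven by methylation kinetics that slow down near the
methylation limits (saturation parameter ``N0``):

    dm/dt = gamma_R * (mtot - m)/(mtot - m + N0) * (1 - A)
          - gamma_B * m/(m + N0) * A.

With ``N0 = 0`` adaptation is perfect (the steady-state activity is the
set-point ``A0`` regardless of stimulus); with ``N0 > 0`` trimers whose
methylation approaches 0 or ``mtot`` adapt imprecisely.  The imprecision in
a mixed Tar/Tsr population is what produces an inversion of the thermal
response (thermophilic at low temperature, cryophilic at high temperature)
when one receptor type is saturated by its chemoattractant.

Module layout follows the order the method runs: parameters and ligand
free energy, team activity, methylation kinetics and steady state,
trimer-ensemble averaging, thermal-response curves, inversion temperature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

__all__ = [
    "TAR",
    "TSR",
    "ModelParams",
    "LigandModel",
    "ReceptorSpec",
    "TrimerComposition",
    "KineticsParams",
    "AdaptedTrimerState",
    "EnsembleState",
    "ThermalResponseCurve",
    "InvalidParameterError",
    "DomainError",
    "NormalizationError",
    "IntegrationError",
    "ligand_free_energy_offset",
    "receptor_free_energy",
    "trimer_activity",
    "trimer_mixing_distribution",
    "methylation_rate",
    "integrate_methylation",
    "steady_state_residual",
    "solve_steady_state_methylation",
    "ensemble_adapted_activity",
    "thermal_response_curve",
    "find_inversion_temperature",
    "default_temperature_grid",
]

TAR = "Tar"
TSR = "Tsr"


class InvalidParameterError(ValueError):
    """A model or kinetics parameter violates its admissible range."""


class DomainError(ValueError):
    """An input (e.g. methylation level) lies outside its domain."""


class NormalizationError(ValueError):
    """The response normalization ΔĀ is not positive."""


class IntegrationError(RuntimeError):
    """Methylation ODE integration failed or produced non-finite values."""


# ---------------------------------------------------------------------------
# Parameters and ligand free energy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Global free-energy and adaptation parameters.

    Attributes
    ----------
    f1 : float
        Temperature slope of the per-dimer free energy (kBT / °C).
    g0 : float
        Methylation coefficient at the reference temperature (kBT per
        methyl group).
    g1 : float
        Temperature slope of the methylation coefficient
        (kBT per methyl group per °C).
    T0 : float
        Reference temperature (°C).
    mtot : int
        Maximum methylation level per receptor dimer.
    N0 : float
        Methylation-saturation parameter; 0 means perfect adaptation.
    A0 : float
        Adapted activity set-point in the absence of saturation, in (0, 1).
    dT_step : float
        Stimulus temperature step used for the thermal response (°C).
    f0_sat : float
        Free-energy offset representing ligand saturation (kBT), used for
        the response normalization.
    """

    f1: float = 1.2
    g0: float = 0.0
    g1: float = 0.2
    T0: float = 24.0
    mtot: int = 8
    N0: float = 2.0
    A0: float = 1.0 / 3.0
    dT_step: float = 3.0
    f0_sat: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.A0 < 1.0):
            raise InvalidParameterError(f"A0 must lie in (0, 1), got {self.A0}")
        if int(self.mtot) != self.mtot or self.mtot < 1:
            raise InvalidParameterError(f"mtot must be a positive integer, got {self.mtot}")
        if self.N0 < 0:
            raise InvalidParameterError(f"N0 must be >= 0, got {self.N0}")
        if self.dT_step <= 0:
            raise InvalidParameterError(f"dT_step must be > 0, got {self.dT_step}")

    def g(self, T: float) -> float:
        """Methylation free-energy coefficient g(T) = g0 + (T - T0) g1."""
        return self.g0 + (T - self.T0) * self.g1


@dataclass(frozen=True)
class LigandModel:
    """Two-state receptor-ligand binding: dissociation constants in the
    active (Kon) and inactive (Koff) states; Koff < Kon for an attractant."""

    f0_zero: float
    Kon: float
    Koff: float
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.Kon <= 0 or self.Koff <= 0:
            raise InvalidParameterError("Kon and Koff must be positive")
        if self.L < 0:
            raise InvalidParameterError("ligand concentration must be >= 0")


def ligand_free_energy_offset(lig: LigandModel) -> float:
    """Effective free-energy offset f0([L]) = f0(0) + ln[(1 + L/Koff)/(1 + L/Kon)].

    For an attractant (Koff < Kon) this increases monotonically with ligand
    concentration, from ``f0_zero`` at L = 0 toward
    ``f0_zero + ln(Kon/Koff)`` at saturation.
    """
    return lig.f0_zero + math.log((1.0 + lig.L / lig.Koff) / (1.0 + lig.L / lig.Kon))


@dataclass(frozen=True)
class ReceptorSpec:
    """A receptor type (Tar or Tsr) with its ligand-dependent offset f0."""

    label: str
    f0: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.f0):
            raise InvalidParameterError("f0 must be finite")

    @classmethod
    def from_ligand(cls, label: str, lig: LigandModel) -> "ReceptorSpec":
        return cls(label=label, f0=ligand_free_energy_offset(lig))


# ---------------------------------------------------------------------------
# Team activity
# ---------------------------------------------------------------------------


def receptor_free_energy(f0, T, m, params: ModelParams, *, check: bool = True):
    """Per-dimer free energy f0 + (T - T0) f1 - [g0 + (T - T0) g1] m (kBT).

    ``m`` may be a scalar or array.  With ``check`` (the default) ``m`` must
    lie in [0, mtot]; internal callers evaluating frozen or unbounded
    methylation states disable the check.
    """
    m = np.asarray(m, dtype=float)
    if check and (np.any(m < 0) or np.any(m > params.mtot)):
        raise DomainError(f"methylation level outside [0, {params.mtot}]")
    out = f0 + (T - params.T0) * params.f1 - params.g(T) * m
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TrimerComposition:
    """Number of Tar dimers (0..3) in a team and its mixing weight."""

    n_tar: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_tar not in (0, 1, 2, 3):
            raise InvalidParameterError(f"n_tar must be in 0..3, got {self.n_tar}")
        if not (0.0 <= self.weight <= 1.0):
            raise InvalidParameterError(f"weight must be in [0, 1], got {self.weight}")


def trimer_mixing_distribution(p_tar: float) -> list[TrimerComposition]:
    """Binomial mixture of trimer compositions for random Tar/Tsr assembly.

    Each of the three dimers in a team is Tar with probability ``p_tar``
    (the relative expression level), so composition ``n_tar`` has weight
    C(3, n) p^n (1-p)^(3-n).  Returned in the order n_tar = 3, 2, 1, 0.
    """
    if not (0.0 <= p_tar <= 1.0):
        raise InvalidParameterError(f"p_tar must be in [0, 1], got {p_tar}")
    comps = [
        TrimerComposition(n, math.comb(3, n) * p_tar**n * (1.0 - p_tar) ** (3 - n))
        for n in (3, 2, 1, 0)
    ]
    assert abs(sum(c.weight for c in comps) - 1.0) < 1e-12
    return comps


def trimer_activity(
    composition: TrimerComposition,
    f0_by_type: dict,
    T: float,
    m,
    params: ModelParams,
    *,
    check: bool = True,
):
    """Activity A = 1/(1 + e^F) of a team, F = n_tar f_Tar + (3 - n_tar) f_Tsr.

    All three dimers share the methylation level ``m``.  Evaluated through
    the logistic in a form that saturates to 0/1 without overflow for
    large |F|.  ``m`` may be an array, in which case an array is returned.
    """
    f_tar = receptor_free_energy(f0_by_type[TAR], T, m, params, check=check)
    f_tsr = receptor_free_energy(f0_by_type[TSR], T, m, params, check=check)
    F = composition.n_tar * np.asarray(f_tar) + (3 - composition.n_tar) * np.asarray(f_tsr)
    A = expit(-F)
    return A if A.ndim else float(A)


# ---------------------------------------------------------------------------
# Methylation kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsParams:
    """Methylation (gamma_R) and demethylation (gamma_B) rate constants.

    Absolute time units are arbitrary; only the ratio matters for the
    steady state.  The default gamma_R/(gamma_R + gamma_B) equals the
    activity set-point A0 = 1/3.
    """

    gamma_R: float = 0.5
    gamma_B: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_R <= 0 or self.gamma_B <= 0:
            raise InvalidParameterError("rate constants must be positive")

    @classmethod
    def for_set_point(cls, A0: float, gamma_B: float = 1.0) -> "KineticsParams":
        """Rates whose N0 = 0 fixed point has activity ``A0``."""
        return cls(gamma_R=gamma_B * A0 / (1.0 - A0), gamma_B=gamma_B)


def _occ(x, N0: float):
    """Saturating occupancy x/(x + N0) with the 0/0 limit taken as 0."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    denom = x + N0
    safe = np.where(denom > 0.0, denom, 1.0)
    out = np.where(denom > 0.0, x / safe, 0.0)
    return out if out.ndim else float(out)


def methylation_rate(m, A, kin: KineticsParams, params: ModelParams):
    """dm/dt from saturating methylation/demethylation kinetics.

    gamma_R (mtot-m)/(mtot-m+N0) (1-A) - gamma_B m/(m+N0) A.  The rate is
    non-negative at m = 0 and non-positive at m = mtot, so [0, mtot] is
    forward-invariant.
    """
    A = np.asarray(A, dtype=float)
    meth = kin.gamma_R * _occ(params.mtot - np.asarray(m, float), params.N0) * (1.0 - A)
    demeth = kin.gamma_B * _occ(m, params.N0) * A
    out = meth - demeth
    return out if np.ndim(out) else float(out)


def integrate_methylation(
    m0: float,
    activity_fn,
    T: float,
    kin: KineticsParams | None = None,
    params: ModelParams | None = None,
    t_end: float = 500.0,
    n_eval: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the methylation ODE with activity re-evaluated each step.

    Parameters
    ----------
    m0 : float
        Initial methylation in [0, mtot].
    activity_fn : callable(m, T) -> float
        Activity of the team at methylation ``m`` and temperature ``T``.
    t_end : float
        Integration horizon in model time units (1/gamma_B scale).

    Returns
    -------
    (t, m) : pair of ndarray
        Sampled times and methylation values, clipped to [0, mtot].
    """
    kin = kin or KineticsParams()
    params = params or ModelParams()
    if not (0.0 <= m0 <= params.mtot):
        raise DomainError(f"m0 outside [0, {params.mtot}]")

    def rhs(t, y):
        m = min(max(y[0], 0.0), float(params.mtot))
        A = float(activity_fn(m, T))
        if not np.isfinite(A):
            raise IntegrationError(f"non-finite activity at m={m}, T={T}")
        return [methylation_rate(m, A, kin, params)]

    t_eval = np.linspace(0.0, t_end, n_eval)
    sol = solve_ivp(rhs, (0.0, t_end), [float(m0)], method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(sol.message)
    return sol.t, np.clip(sol.y[0], 0.0, float(params.mtot))


# ---------------------------------------------------------------------------
# Adapted steady state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdaptedTrimerState:
    """Adapted methylation and activity of one trimer composition.

    ``boundary`` marks solutions pinned at m = 0 or m = mtot (or a
    degenerate case where activity does not depend on m), where the
    steady-state balance cannot be satisfied in the interior.  For the
    perfect-adaptation (N0 = 0, unbounded-m) variant ``m_ss`` may lie
    outside [0, mtot] by construction.
    """

    composition: TrimerComposition
    T: float
    m_ss: float
    A: float
    boundary: bool = False


def steady_state_residual(m, composition, f0_by_type, T, params: ModelParams):
    """Residual h(m) of the adapted-state balance; h(m_ss) = 0.

    h(m) = (mtot-m)/(mtot-m+N0) (1-A(m))/(1-A0) - m/(m+N0) A(m)/A0.
    h(0) > 0 and h(mtot) < 0 for finite free energies, so a root is always
    bracketed on [0, mtot].  Vectorized over ``m``.
    """
    A = trimer_activity(composition, f0_by_type, T, m, params, check=False)
    m = np.asarray(m, dtype=float)
    lhs = _occ(params.mtot - m, params.N0) * (1.0 - A) / (1.0 - params.A0)
    rhs = _occ(m, params.N0) * A / params.A0
    out = lhs - rhs
    return out if np.ndim(out) else float(out)


_BISECT_TOL = 1e-12
_BISECT_MAXITER = 200


def _solve_unbounded(composition, f0_by_type, T, params: ModelParams) -> AdaptedTrimerState:
    # Perfect adaptation: A(m_ss) = A0 exactly, m unconstrained. F is linear
    # in m, so the solution is closed-form. At g(T) <= 0 activity does not
    # depend on m; take the limit by adapting just above T0.
    g = params.g(T)
    T_adapt = T
    if g <= 0.0:
        if params.g1 <= 0.0:
            raise DomainError("g(T) <= 0 for all T: activity independent of methylation")
        T_adapt = params.T0 + 1e-6 if T <= params.T0 else T
        g = params.g(T_adapt)
        warnings.warn(
            f"g(T) <= 0 at T={T}; adapted state evaluated in the limit T -> T0+",
            RuntimeWarning,
            stacklevel=3,
        )
    F0 = composition.n_tar * f0_by_type[TAR] + (3 - composition.n_tar) * f0_by_type[TSR]
    F_target = math.log((1.0 - params.A0) / params.A0)
    m_ss = (F0 + 3.0 * (T_adapt - params.T0) * params.f1 - F_target) / (3.0 * g)
    return AdaptedTrimerState(composition, T, m_ss=m_ss, A=params.A0, boundary=False)


def solve_steady_state_methylation(
    composition: TrimerComposition,
    f0_by_type: dict,
    T: float,
    params: ModelParams | None = None,
    *,
    unbounded: bool | None = None,
) -> AdaptedTrimerState:
    """Adapted methylation m_ss and activity of one trimer composition.

    Solves h(m_ss) = 0 (see :func:`steady_state_residual`) by bisection on
    [0, mtot].  ``unbounded`` selects the perfect-adaptation variant where
    methylation is not clipped to [0, mtot] and the adapted activity equals
    A0 exactly; it defaults to True when ``params.N0 == 0``.
    """
    params = params or ModelParams()
    if unbounded is None:
        unbounded = params.N0 == 0.0
    if unbounded:
        if params.N0 != 0.0:
            raise InvalidParameterError("unbounded-m variant requires N0 = 0")
        return _solve_unbounded(composition, f0_by_type, T, params)

    mtot = float(params.mtot)

    def h(m):
        return steady_state_residual(m, composition, f0_by_type, T, params)

    a, b = 0.0, mtot
    ha = h(a)
    if ha <= 0.0:  # pinned at the lower boundary (ties resolved to lower m)
        return AdaptedTrimerState(
            composition, T, 0.0,
            float(trimer_activity(composition, f0_by_type, T, 0.0, params)),
            boundary=True,
        )
    for _ in range(_BISECT_MAXITER):
        if b - a < _BISECT_TOL:
            break
        c = 0.5 * (a + b)
        if h(c) > 0.0:
            a = c
        else:
            b = c
    m_ss = 0.5 * (a + b)
    A = float(trimer_activity(composition, f0_by_type, T, m_ss, params))
    residual = h(m_ss)
    boundary = abs(residual) > 1e-8 and (m_ss < 1e-9 or mtot - m_ss < 1e-9)
    return AdaptedTrimerState(composition, T, m_ss, A, boundary=boundary)


# ---------------------------------------------------------------------------
# Trimer-ensemble averaging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleState:
    """Adapted states of the four trimer compositions and the average
    activity Ā weighted by the binomial mixing distribution."""

    states: tuple[AdaptedTrimerState, ...]
    A_bar: float

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(s.composition.weight for s in self.states)

    @property
    def m_ss(self) -> tuple[float, ...]:
        return tuple(s.m_ss for s in self.states)


def ensemble_adapted_activity(
    p_tar: float,
    f0_by_type: dict,
    T: float,
    params: ModelParams | None = None,
    *,
    unbounded: bool | None = None,
) -> EnsembleState:
    """Adapt every trimer composition independently and average the activity.

    Each trimer adapts to its own methylation level (all three dimers in a
    team share one m); the population average Ā weights the four
    compositions by the binomial mixing distribution for ``p_tar``.
    """
    params = params or ModelParams()
    comps = trimer_mixing_distribution(p_tar)
    states = tuple(
        solve_steady_state_methylation(c, f0_by_type, T, params, unbounded=unbounded)
        for c in comps
    )
    A_bar = float(sum(s.composition.weight * s.A for s in states))
    return EnsembleState(states=states, A_bar=A_bar)


# ---------------------------------------------------------------------------
# Thermal-response curves
# ---------------------------------------------------------------------------


def default_temperature_grid() -> np.ndarray:
    """Default grid 24..39 °C in 3 °C steps."""
    return np.arange(24.0, 39.0 + 1e-9, 3.0)


@dataclass
class ThermalResponseCurve:
    """Normalized thermal response R(T) on a temperature grid.

    R(T) = [Ā(T + dT) - Ā(T)] / ΔĀ, with ΔĀ the activity drop at the
    lowest grid temperature upon ligand saturation.  R < 0 is thermophilic
    (kinase activity falls on warming, attractant-like); R > 0 cryophilic.
    """

    T_grid: np.ndarray
    R: np.ndarray
    delta_A_norm: float
    classes: list[str]
    A_bar: np.ndarray
    m_ss: np.ndarray  # shape (len(T_grid), 4), order n_tar = 3, 2, 1, 0
    T_inv: float | None = None
    mode: str = "transient"
    tol: float = 1e-6

    def to_dataframe(self):
        import pandas as pd

        cols = {"T_celsius": self.T_grid, "R": self.R, "class": self.classes}
        for j, n_tar in enumerate((3, 2, 1, 0)):
            cols[f"m_ss_ntar{n_tar}"] = self.m_ss[:, j]
        cols["A_bar"] = self.A_bar
        return pd.DataFrame(cols)


def _frozen_activity(states, f0_by_type, T, params) -> float:
    """Ā at temperature T with each trimer's methylation frozen."""
    return float(
        sum(
            s.composition.weight
            * trimer_activity(s.composition, f0_by_type, T, s.m_ss, params, check=False)
            for s in states
        )
    )


def thermal_response_curve(
    p_tar: float,
    f0_by_type: dict,
    T_grid=None,
    params: ModelParams | None = None,
    mode: str = "transient",
    norm_receptor: str = TAR,
    tol: float = 1e-6,
    *,
    unbounded: bool | None = None,
) -> ThermalResponseCurve:
    """Normalized thermal response R(T) = [Ā(T + dT) - Ā(T)] / ΔĀ.

    In the default ``mode="transient"``, Ā(T + dT) is evaluated with each
    trimer's methylation frozen at its T-adapted value — the initial
    response amplitude a FRET measurement reports before re-adaptation.
    ``mode="re_adapted"`` instead lets the ensemble re-adapt at T + dT
    (identically zero under perfect adaptation).

    The normalization ΔĀ is the activity change at the lowest grid
    temperature when the ``norm_receptor`` (default Tar) is driven from the
    no-ligand adapted state to ligand saturation (f0 = f0_sat) with
    methylation frozen.
    """
    params = params or ModelParams()
    if mode not in ("transient", "re_adapted"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    T_grid = np.asarray(default_temperature_grid() if T_grid is None else T_grid, float)
    if T_grid.ndim != 1 or len(T_grid) < 1 or np.any(np.diff(T_grid) <= 0):
        raise InvalidParameterError("T_grid must be 1-D and strictly ascending")
    dT = params.dT_step
    T_min = float(T_grid[0])

    # Normalization: adapted, ligand-free ensemble at T_min, then saturate
    # the chosen receptor with methylation frozen.
    no_ligand = {TAR: 0.0, TSR: 0.0}
    ens0 = ensemble_adapted_activity(p_tar, no_ligand, T_min, params, unbounded=unbounded)
    saturated = dict(no_ligand)
    saturated[norm_receptor] = params.f0_sat
    A_sat = _frozen_activity(ens0.states, saturated, T_min, params)
    delta_A = ens0.A_bar - A_sat
    if delta_A <= 0.0:
        raise NormalizationError(f"ΔĀ = {delta_A} is not positive")

    R = np.empty(len(T_grid))
    A_bar = np.empty(len(T_grid))
    m_ss = np.empty((len(T_grid), 4))
    for i, T in enumerate(T_grid):
        ens = ensemble_adapted_activity(p_tar, f0_by_type, float(T), params, unbounded=unbounded)
        A_bar[i] = ens.A_bar
        m_ss[i] = ens.m_ss
        if mode == "transient":
            A_next = _frozen_activity(ens.states, f0_by_type, float(T) + dT, params)
        else:
            A_next = ensemble_adapted_activity(
                p_tar, f0_by_type, float(T) + dT, params, unbounded=unbounded
            ).A_bar
        R[i] = (A_next - ens.A_bar) / delta_A

    classes = [
        "thermophilic" if r < -tol else ("cryophilic" if r > tol else "none") for r in R
    ]
    curve = ThermalResponseCurve(
        T_grid=T_grid, R=R, delta_A_norm=delta_A, classes=classes,
        A_bar=A_bar, m_ss=m_ss, mode=mode, tol=tol,
    )
    curve.T_inv = find_inversion_temperature(curve)
    return curve


def find_inversion_temperature(curve: ThermalResponseCurve) -> float | None:
    """Temperature at which R(T) changes sign, or None.

    Locates the first adjacent grid pair with a strict sign change and
    returns the linearly interpolated zero crossing.
    """
    R, T = curve.R, curve.T_grid
    for i in range(len(R) - 1):
        if R[i] * R[i + 1] < 0.0:
            frac = R[i] / (R[i] - R[i + 1])
            return float(T[i] + frac * (T[i + 1] - T[i]))
    return None
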