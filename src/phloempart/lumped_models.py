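"""Lumped two-sink partitioning models: VK (no resistance) and VKR.

The VK model assumes a perfectly conducting pathway: source and sink sucrose
concentrations are equal and partitioning follows from the Michaelis-Menten
unloading kinetics alone.  The VKR model adds a lumped pathway resistance
per sink whose value depends on the sucrose concentration halfway along the
pathway through a quartic viscosity polynomial (valid for 0-1.5 M); the
steady state couples the resistive delivery flux ``c0*(c0 - ci)/ri`` to the
unloading kinetics of each sink.

Concentrations are mol/m^3 throughout; the viscosity polynomial alone takes
molar units (mol/L) and the conversion happens inside
:func:`vkr_resistance`.  Resistances are mol s m^-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VISCOSITY_POLY",
    "VKSolution",
    "VKRSolution",
    "NoSteadyStateError",
    "vk_solve",
    "vkr_resistance",
    "vkr_solve",
    "lumped_scan",
    "SCAN_COLUMNS",
]

#: Coefficients (descending powers of S in mol/L) of the sucrose-viscosity
#: polynomial used for the lumped resistance.
VISCOSITY_POLY = np.array([0.685, -1.0411, 0.9512, 0.1364, 0.3396])

#: Validity range of the polynomial, mol/L.
VISCOSITY_POLY_RANGE = (0.0, 1.5)


class NoSteadyStateError(RuntimeError):
    """Raised when the demanded loading rate exceeds total sink capacity."""


@dataclass
class VKSolution:
    c: float            # shared concentration, mol/m^3
    v1: float           # mol/s
    v2: float
    pc1: float

    @property
    def pc2(self) -> float:
        return 1.0 - self.pc1


@dataclass
class VKRSolution:
    c0: float
    c1: float
    c2: float
    v1: float
    v2: float
    r1_eff: float       # sucrose-adjusted resistances, mol s m^-6
    r2_eff: float
    pc1: float
    residual: float
    all_roots: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def pc2(self) -> float:
        return 1.0 - self.pc1


def _check_capacity(v0: float, sinks) -> None:
    total = sum(vm for vm, _ in sinks)
    if v0 >= total:
        raise NoSteadyStateError(
            f"loading rate {v0:g} mol/s is not below the combined sink "
            f"capacity {total:g} mol/s; no steady state exists")
    if v0 < 0:
        raise ValueError("loading rate must be >= 0")


def vk_solve(v0: float, sinks: list[tuple[float, float]]) -> VKSolution:
    """Solve the no-resistance model for two sinks.

    ``sinks`` is ``[(v_max_1, k_1), (v_max_2, k_2)]`` in mol/s and mol/m^3.
    The shared concentration is the unique positive root of
    ``sum_i v_max_i * c / (c + k_i) = v0``; with equal affinities it is the
    closed form ``c = K * v0 / (sum v_max - v0)``.
    """
    (vm1, k1), (vm2, k2) = sinks
    _check_capacity(v0, sinks)
    if v0 == 0:
        return VKSolution(c=0.0, v1=0.0, v2=0.0, pc1=float("nan"))
    if k1 == k2:
        c = k1 * v0 / (vm1 + vm2 - v0)
    else:
        def f(c):
            return vm1 * c / (c + k1) + vm2 * c / (c + k2) - v0
        hi = max(k1, k2) * v0 / (vm1 + vm2 - v0) + max(k1, k2)
        while f(hi) < 0:
            hi *= 2
        c = optimize.brentq(f, 0.0, hi, xtol=1e-300, rtol=8.9e-16)
    v1 = vm1 * c / (c + k1)
    v2 = vm2 * c / (c + k2)
    return VKSolution(c=c, v1=v1, v2=v2, pc1=v1 / (v1 + v2))


def vkr_resistance(
    s_half: float | np.ndarray,
    r_ref: float,
    out_of_range: str = "warn",
) -> float | np.ndarray:
    """Sucrose-dependent lumped resistance, ``r_ref * poly(S_1/2)``.

    ``s_half`` is the mid-pathway sucrose concentration in mol/L (molar
    units).  The quartic is printed for 0 <= S <= 1.5 M; outside that range
    the default policy evaluates anyway and warns (``out_of_range="clamp"``
    clamps S into the validity interval instead).
    """
    s = np.asarray(s_half, dtype=float)
    lo, hi = VISCOSITY_POLY_RANGE
    if np.any((s < lo) | (s > hi)):
        if out_of_range == "warn":
            warnings.warn(
                "mid-pathway sucrose concentration outside the 0-1.5 M "
                "validity range of the viscosity polynomial", stacklevel=2)
        elif out_of_range == "clamp":
            s = np.clip(s, lo, hi)
    value = r_ref * np.polyval(VISCOSITY_POLY, s)
    return float(value) if np.isscalar(s_half) else value


def _vkr_residuals(x, v0, sinks, r_refs, poly_policy="clamp"):
    c0, c1, c2 = x
    (vm1, k1), (vm2, k2) = sinks
    r1 = vkr_resistance((c0 + c1) / 2 / 1000.0, r_refs[0], out_of_range=poly_policy)
    r2 = vkr_resistance((c0 + c2) / 2 / 1000.0, r_refs[1], out_of_range=poly_policy)
    u1 = vm1 * c1 / (k1 + c1)
    u2 = vm2 * c2 / (k2 + c2)
    return np.array([
        c0 * (c0 - c1) / r1 - u1,
        c0 * (c0 - c2) / r2 - u2,
        u1 + u2 - v0,
    ])


def vkr_solve(
    v0: float,
    sinks: list[tuple[float, float]],
    r_refs: tuple[float, float],
    x0: tuple[float, float, float] | None = None,
    residual_tol: float = 1e-13,
    poly_policy: str = "clamp",
) -> VKRSolution:
    """Solve the VKR steady state for two sinks.

    Unknowns are the source and sink concentrations ``(c0, c1, c2)``
    (mol/m^3).  Per sink the resistive delivery flux equals the unloading
    rate, with the resistance evaluated at the mid-pathway concentration
    ``(c0 + ci)/2``; total unloading equals the loading rate.  Multi-start
    root finding; only biologically valid roots (all concentrations
    positive) are accepted and, if several exist, the smallest-``c0`` root
    is returned with all roots recorded.

    The viscosity polynomial is by default clamped at its 1.5 M validity
    limit (``poly_policy="clamp"``): extrapolating the quartic to the
    multi-molar concentrations reached near sink saturation makes the
    resistance grow ~S^4, faster than the ~c0^2 driving term, so steady
    states would cease to exist within the standard loading range.
    """
    _check_capacity(v0, sinks)
    (vm1, k1), (vm2, k2) = sinks

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    # VK solution as an anchor for the low-resistance regime
    try:
        vk = vk_solve(v0, sinks)
        if vk.c > 0:
            starts.append(np.array([vk.c * 1.5, vk.c, vk.c]))
    except NoSteadyStateError:  # pragma: no cover - guarded above
        pass
    for c0_guess in (1.0, 10.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0):
        starts.append(np.array([c0_guess, 0.5 * c0_guess, 0.5 * c0_guess]))
        starts.append(np.array([c0_guess, 0.9 * c0_guess, 0.1 * c0_guess]))

    roots: list[np.ndarray] = []
    best_res = np.inf
    for s in starts:
        sol = optimize.root(
            _vkr_residuals, s, args=(v0, sinks, r_refs, poly_policy),
            method="hybr", options={"xtol": 1e-14, "maxfev": 4000})
        res = float(np.max(np.abs(
            _vkr_residuals(sol.x, v0, sinks, r_refs, poly_policy))))
        best_res = min(best_res, res)
        if res < residual_tol and np.all(sol.x > 0):
            if not any(np.allclose(sol.x, r, rtol=1e-6) for r in roots):
                roots.append(sol.x)
    if not roots:
        raise RuntimeError(
            f"VKR solver did not converge (best residual {best_res:.3e} mol/s "
            f"exceeds {residual_tol:g})")

    roots.sort(key=lambda r: r[0])
    c0, c1, c2 = roots[0]
    r1 = vkr_resistance((c0 + c1) / 2 / 1000.0, r_refs[0], out_of_range=poly_policy)
    r2 = vkr_resistance((c0 + c2) / 2 / 1000.0, r_refs[1], out_of_range=poly_policy)
    v1 = vm1 * c1 / (k1 + c1)
    v2 = vm2 * c2 / (k2 + c2)
    res = float(np.max(np.abs(
        _vkr_residuals(roots[0], v0, sinks, r_refs, poly_policy))))
    return VKRSolution(
        c0=c0, c1=c1, c2=c2, v1=v1, v2=v2, r1_eff=float(r1), r2_eff=float(r2),
        pc1=v1 / (v1 + v2), residual=res,
        all_roots=[tuple(r) for r in roots])


SCAN_COLUMNS = ["v0", "c0", "c1", "c2", "v1", "v2", "pc1",
                "r1_eff", "r2_eff", "physiological_flag", "converged"]


def lumped_scan(
    model: str,
    loading_grid,
    sinks: list[tuple[float, float]],
    r_refs: tuple[float, float] = (7.5e12, 7.5e12),
) -> pd.DataFrame:
    """Steady-state scan of a lumped model over a loading-rate grid.

    ``model`` is ``"vk"`` or ``"vkr"``.  Each VKR solve warm-starts from the
    previous root; per-row failures are recorded (``converged=False``)
    without aborting the scan.  The physiological flag marks source
    concentrations between 0.1 and 2 M.
    """
    if model not in ("vk", "vkr"):
        raise ValueError("model must be 'vk' or 'vkr'")
    grid = np.asarray(list(loading_grid), dtype=float)
    if grid.size and np.any(np.diff(grid) <= 0):
        raise ValueError("loading grid must be strictly increasing")
    rows = []
    warm = None
    for v0 in grid:
        row = dict.fromkeys(SCAN_COLUMNS, np.nan)
        row["v0"] = v0
        row["converged"] = False
        try:
            if model == "vk":
                sol = vk_solve(v0, sinks)
                row.update(c0=sol.c, c1=sol.c, c2=sol.c, v1=sol.v1, v2=sol.v2,
                           pc1=sol.pc1, r1_eff=0.0, r2_eff=0.0, converged=True)
                c0 = sol.c
            else:
                sol = vkr_solve(v0, sinks, r_refs, x0=warm)
                warm = (sol.c0, sol.c1, sol.c2)
                row.update(c0=sol.c0, c1=sol.c1, c2=sol.c2, v1=sol.v1,
                           v2=sol.v2, pc1=sol.pc1, r1_eff=sol.r1_eff,
                           r2_eff=sol.r2_eff, converged=True)
                c0 = sol.c0
            row["physiological_flag"] = bool(100.0 < c0 < 2000.0)
        except (NoSteadyStateError, RuntimeError):
            pass
        rows.append(row)
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)
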