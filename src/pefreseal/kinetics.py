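"""Closed-form and numerical kinetics of TPP+ uptake and membrane fluorescence.

The cell-wall model is a pseudo-second-order absorption law

    dN/dt = k_a(t) * (N_m - N) * (N_s - N),        N(0) = 0,

where the absorption coefficient carries an exponentially decaying
contribution from pulse-induced transient wall pores,

    k_a(t) = k_a0 + A * exp(-dt/tau_d) * exp(-t/tau_d),

with ``dt`` the delay between the pulse and the addition of the probe ion.
Because ``k_a`` is separable in time, the ODE integrates in closed form:
with the accumulated rate integral K(t) = int_0^t k_a(u) du, the absorbed
amount is

    N(t) = N_m * (1 - S) / (1 - R*S),   S = exp((N_m - N_s) * K),  R = N_m/N_s.

The membrane model is a plain exponential-plus-residual fluorescence decay
I(dt) = I0 * exp(-dt/tau_l) + I_r.

A fixed-step RK4 integrator of the original ODE is provided as an
independent numerical oracle for the closed form.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .errors import DomainError, ValidationError
from .params import (
    FieldResponseParams,
    MembraneFluorescenceParams,
    PulseSpec,
    UptakeConstants,
    WallPoreParams,
)

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "pef_amplitude",
    "pore_excess",
    "absorption_rate",
    "accumulated_rate",
    "rate_integral_from_fraction",
    "uptake_closed_form",
    "uptake_with_delay",
    "baseline_uptake",
    "fluorescence_intensity",
    "integrate_uptake_ode",
]


def _as_nonnegative(t: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValidationError(f"{name} must be >= 0 s")
    return arr


def _maybe_scalar(arr: np.ndarray, *inputs: ArrayLike) -> ArrayLike:
    if all(np.isscalar(x) or np.ndim(x) == 0 for x in inputs):
        return float(arr)
    return arr


def pef_amplitude(field_response: FieldResponseParams, pulse: PulseSpec) -> float:
    """Pore-term amplitude A as a function of field strength and pulse length.

    A = b * (E_p - E_th_p)^2 * f^2 * [1 - exp(-t_p/t_ch)]^2 for fields above
    the permeabilization threshold, and exactly 0 at or below it.  The
    saturating (negative-exponent) membrane-charging bracket is used.
    Units: uM^-1 s^-1.
    """
    dE = pulse.E_p - field_response.E_th_p
    if dE <= 0.0:
        return 0.0
    bracket = 1.0 - math.exp(-pulse.t_p / field_response.t_ch)
    return field_response.b * dE * dE * field_response.f**2 * bracket * bracket


def pore_excess(A: float, tau_d: float, t: ArrayLike) -> ArrayLike:
    """Excess absorption-rate contribution of transient pores at time ``t``.

    A * exp(-t/tau_d); strictly decreasing in ``t`` for A > 0.
    """
    if not (math.isfinite(A) and A >= 0):
        raise ValidationError("A must be >= 0")
    if not (math.isfinite(tau_d) and tau_d > 0):
        raise ValidationError("tau_d must be > 0 s")
    tt = _as_nonnegative(t, "t")
    return _maybe_scalar(A * np.exp(-tt / tau_d), t)


def absorption_rate(wall: WallPoreParams, t: ArrayLike) -> ArrayLike:
    """Absorption coefficient k_a(t) = k_a0 + A*exp(-t/tau_d), uM^-1 s^-1."""
    return _maybe_scalar(
        np.asarray(wall.k_a0 + pore_excess(wall.A, wall.tau_d, t)), t
    )


def accumulated_rate(wall: WallPoreParams, t: ArrayLike, delta_t: float = 0.0) -> ArrayLike:
    """Accumulated rate integral K(t) = int_0^t k_a(u) du, uM^-1.

    With a post-pulse delay ``delta_t`` before the probe is added the pore
    amplitude has already decayed by exp(-delta_t/tau_d):

        K(t) = k_a0*t + A*tau_d*exp(-delta_t/tau_d)*(1 - exp(-t/tau_d)).
    """
    tt = _as_nonnegative(t, "t")
    dt = _as_nonnegative(delta_t, "delta_t")
    decayed = wall.A * math.exp(-float(dt) / wall.tau_d) if np.ndim(dt) == 0 else wall.A * np.exp(-dt / wall.tau_d)
    K = wall.k_a0 * tt + decayed * wall.tau_d * (1.0 - np.exp(-tt / wall.tau_d))
    return _maybe_scalar(np.asarray(K), t, delta_t)


def _check_two_root_domain(constants: UptakeConstants) -> None:
    if not constants.equal_roots and constants.N_m >= constants.N_s:
        raise DomainError(
            "uptake closed form requires N_m < N_s "
            f"(got N_m={constants.N_m}, N_s={constants.N_s})"
        )


def _fraction_from_K(constants: UptakeConstants, K: ArrayLike) -> np.ndarray:
    """Absorbed fraction N/N_m for an accumulated rate integral K >= 0."""
    Karr = np.asarray(K, dtype=float)
    if constants.equal_roots:
        # limit solution of dN/dt = k_a (N_m - N)^2
        x = constants.N_m * Karr
        return x / (1.0 + x)
    _check_two_root_domain(constants)
    S = np.exp((constants.N_m - constants.N_s) * Karr)
    R = constants.capacity_ratio
    return (1.0 - S) / (1.0 - R * S)


def rate_integral_from_fraction(constants: UptakeConstants, fraction: float) -> float:
    """Invert the closed form: K such that N/N_m equals ``fraction``.

    Used by anchor calibration.  Requires 0 <= fraction < 1.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValidationError("fraction must lie in [0, 1)")
    if constants.equal_roots:
        return fraction / (constants.N_m * (1.0 - fraction))
    _check_two_root_domain(constants)
    R = constants.capacity_ratio
    S = (1.0 - fraction) / (1.0 - R * fraction)
    return math.log(S) / (constants.N_m - constants.N_s)


def uptake_closed_form(
    constants: UptakeConstants, wall: WallPoreParams, t: ArrayLike
) -> ArrayLike:
    """Absorbed TPP+ amount N(t) in uM with the probe added at the pulse.

    N(0) = 0; strictly increasing in ``t`` when k_a0 > 0; bounded by N_m.
    """
    K = accumulated_rate(wall, t, delta_t=0.0)
    return _maybe_scalar(constants.N_m * _fraction_from_K(constants, K), t)


def uptake_with_delay(
    constants: UptakeConstants,
    wall: WallPoreParams,
    t: ArrayLike,
    delta_t: ArrayLike,
) -> ArrayLike:
    """Absorbed fraction N/N_m after incubating ``t`` seconds, the probe
    having been added ``delta_t`` seconds after the pulse.

    Monotone non-increasing in ``delta_t``; reduces to
    ``uptake_closed_form / N_m`` at ``delta_t = 0`` and converges to
    :func:`baseline_uptake` as ``delta_t -> inf``.
    """
    tt = _as_nonnegative(t, "t")
    dt = _as_nonnegative(delta_t, "delta_t")
    K = (
        wall.k_a0 * tt
        + wall.A * np.exp(-dt / wall.tau_d) * wall.tau_d * (1.0 - np.exp(-tt / wall.tau_d))
    )
    return _maybe_scalar(_fraction_from_K(constants, K), t, delta_t)


def baseline_uptake(constants: UptakeConstants, k_a0: float, t: ArrayLike) -> ArrayLike:
    """Absorbed fraction N0/N_m of untreated cells (no pore term)."""
    if not (math.isfinite(k_a0) and k_a0 >= 0):
        raise ValidationError("k_a0 must be >= 0")
    tt = _as_nonnegative(t, "t")
    return _maybe_scalar(_fraction_from_K(constants, k_a0 * tt), t)


def fluorescence_intensity(
    params: MembraneFluorescenceParams, delta_t: ArrayLike
) -> ArrayLike:
    """Fluorescence intensity I0*exp(-delta_t/tau_l) + I_r, arbitrary units."""
    dt = _as_nonnegative(delta_t, "delta_t")
    return _maybe_scalar(params.I0 * np.exp(-dt / params.tau_l) + params.I_r, delta_t)


def integrate_uptake_ode(
    constants: UptakeConstants,
    wall: WallPoreParams,
    delta_t: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Fixed-step RK4 integration of the uptake ODE on ``t_grid``.

    Serves as the independent numerical oracle for the closed form.  The
    step is at most 0.01 * min(tau_d, 1/(k_a_max * N_s)), with
    k_a_max = k_a0 + A*exp(-delta_t/tau_d), so the integration is
    deterministic and reproducible bit-for-bit.

    ``t_grid`` must start at 0 and be strictly increasing; returns the
    absorbed amount N at every grid point (N(0) = 0).
    """
    grid = np.asarray(t_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValidationError("t_grid must be a 1-d array of times")
    if grid[0] != 0.0:
        raise ValidationError("t_grid must start at 0")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("t_grid must be strictly increasing")
    dt0 = float(_as_nonnegative(delta_t, "delta_t"))

    a_eff = wall.A * math.exp(-dt0 / wall.tau_d)
    k_a_max = wall.k_a0 + a_eff
    h_max = 0.01 * wall.tau_d
    if k_a_max > 0:
        h_max = min(h_max, 0.01 / (k_a_max * constants.N_s))

    def rate(t: float, N: float) -> float:
        k_a = wall.k_a0 + a_eff * math.exp(-t / wall.tau_d)
        return k_a * (constants.N_m - N) * (constants.N_s - N)

    out = np.empty_like(grid)
    out[0] = 0.0
    N = 0.0
    for i in range(1, grid.size):
        t0, t1 = grid[i - 1], grid[i]
        n_sub = max(1, math.ceil((t1 - t0) / h_max))
        h = (t1 - t0) / n_sub
        t = t0
        for _ in range(n_sub):
            k1 = rate(t, N)
            k2 = rate(t + 0.5 * h, N + 0.5 * h * k1)
            k3 = rate(t + 0.5 * h, N + 0.5 * h * k2)
            k4 = rate(t + h, N + h * k3)
            N += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[i] = N
    return out
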