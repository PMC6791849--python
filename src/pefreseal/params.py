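"""Parameter containers for the resealing-kinetics models.

Units are fixed package-wide: time in seconds (pulse durations in
microseconds, converted where needed), electric field strength in kV/cm,
concentrations in uM, absorption rate coefficients in uM^-1 s^-1 and
fluorescence in arbitrary units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

#: Relative tolerance below which N_m and N_s are treated as equal and the
#: equal-roots limit of the uptake solution is used.
EQUAL_ROOTS_RTOL = 1e-9


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass(frozen=True)
class PulseSpec:
    """A single square electric pulse.

    Parameters
    ----------
    E_p:
        Electric field strength amplitude, kV/cm.
    t_p:
        Pulse duration, microseconds.
    """

    E_p: float
    t_p: float = 150.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.E_p) and self.E_p >= 0, "E_p must be >= 0 kV/cm")
        _require(math.isfinite(self.t_p) and self.t_p > 0, "t_p must be > 0 us")


@dataclass(frozen=True)
class UptakeConstants:
    """Capacity constants of the pseudo-second-order TPP+ uptake law.

    ``N_m`` is the maximal amount of TPP+ the cell suspension can
    accumulate during the slow absorption stage; ``N_s`` is the TPP+
    pool concentration at the start of that stage.  The two-root closed
    form requires ``N_m < N_s`` (the absorbed amount saturates below the
    available pool); the near-degenerate case ``N_m ~ N_s`` is handled
    by an equal-roots limit, see :mod:`pefreseal.kinetics`.
    """

    N_m: float = 0.5
    N_s: float = 1.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.N_m) and self.N_m > 0, "N_m must be > 0 uM")
        _require(math.isfinite(self.N_s) and self.N_s > 0, "N_s must be > 0 uM")

    @property
    def capacity_ratio(self) -> float:
        """R = N_m / N_s, dimensionless."""
        return self.N_m / self.N_s

    @property
    def equal_roots(self) -> bool:
        """True when |N_m - N_s| is below the equal-roots tolerance."""
        return abs(self.N_m - self.N_s) < EQUAL_ROOTS_RTOL * self.N_s


@dataclass(frozen=True)
class WallPoreParams:
    """Time-dependent absorption coefficient of the cell wall.

    ``k_a0`` is the baseline absorption coefficient of untreated cells,
    ``A`` the amplitude of the pulse-induced excess (the identifiable
    product of the pore-count-to-rate constant and the initial excess
    pore count) and ``tau_d`` the characteristic lifetime of the
    pulse-induced transient wall pores.
    """

    k_a0: float
    A: float
    tau_d: float

    def __post_init__(self) -> None:
        _require(math.isfinite(self.k_a0) and self.k_a0 >= 0, "k_a0 must be >= 0")
        _require(math.isfinite(self.A) and self.A >= 0, "A must be >= 0")
        _require(math.isfinite(self.tau_d) and self.tau_d > 0, "tau_d must be > 0 s")


@dataclass(frozen=True)
class FieldResponseParams:
    """Parametric field dependence of the pore-term amplitude.

    ``b`` is the empirical field-effectiveness constant, ``E_th_p`` the
    threshold field strength below which no excess pores are created,
    ``t_ch`` the membrane charging time (microseconds) and ``f`` the cell
    shape factor (1.5 for spheres).
    """

    b: float
    E_th_p: float
    t_ch: float
    f: float = 1.5

    def __post_init__(self) -> None:
        _require(math.isfinite(self.b) and self.b >= 0, "b must be >= 0")
        _require(math.isfinite(self.E_th_p) and self.E_th_p >= 0, "E_th_p must be >= 0")
        _require(math.isfinite(self.t_ch) and self.t_ch > 0, "t_ch must be > 0 us")
        _require(math.isfinite(self.f) and self.f > 0, "f must be > 0")


@dataclass(frozen=True)
class MembraneFluorescenceParams:
    """Exponential-plus-residual model of post-pulse dye fluorescence.

    ``I0`` is the decaying amplitude at zero delay, ``I_r`` the residual
    plateau intensity and ``tau_l`` the characteristic decay time of the
    lipidic (membrane) pores.  Intensities are in arbitrary units.
    """

    I0: float
    I_r: float
    tau_l: float

    def __post_init__(self) -> None:
        _require(math.isfinite(self.I0) and self.I0 >= 0, "I0 must be >= 0")
        _require(math.isfinite(self.I_r) and self.I_r >= 0, "I_r must be >= 0")
        _require(math.isfinite(self.tau_l) and self.tau_l > 0, "tau_l must be > 0 s")
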