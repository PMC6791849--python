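"""Synthetic datasets with the structure of the three experimental designs.

Three designs are emulated, all on the study's grids:

* fluorescence — membrane-resealing dye intensity at six post-pulse delays
  {10, 30, 90, 180, 360, 600} s;
* uptake — absorbed TPP+ fraction after a 180 s incubation, probe added at
  ten post-pulse delays {5, 10, 20, 30, 40, 50, 60, 80, 120, 180} s, for
  the three field strengths {2.93, 4.38, 5.85} kV/cm (150 us pulses);
* trace — the raw ion-selective-electrode concentration trace with its
  three stages (fast surface adsorption, delay plateau, slow absorption);
  the delay stage is absent when a pulse was applied.

Noise is additive Gaussian on the reported quantity.  One master seed
spawns an independent, deterministic stream per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import FluorescenceSeries, UptakeRecoveryDataset
from .errors import ValidationError
from .kinetics import fluorescence_intensity, uptake_closed_form, uptake_with_delay
from .params import MembraneFluorescenceParams, UptakeConstants, WallPoreParams

__all__ = [
    "DEFAULT_FLUOR_DELAYS",
    "DEFAULT_UPTAKE_DELAYS",
    "DEFAULT_FIELDS",
    "DEFAULT_INCUBATION_T",
    "DEFAULT_PULSE_DURATION_US",
    "DEFAULT_SIGMA_RATIO",
    "DEFAULT_SIGMA_FLUOR",
    "NoiseSpec",
    "TraceStageSpec",
    "generate_fluorescence_series",
    "generate_uptake_dataset",
    "generate_electrode_trace",
]

DEFAULT_FLUOR_DELAYS = (10.0, 30.0, 90.0, 180.0, 360.0, 600.0)
DEFAULT_UPTAKE_DELAYS = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 120.0, 180.0)
DEFAULT_FIELDS = (2.93, 4.38, 5.85)
DEFAULT_INCUBATION_T = 180.0
DEFAULT_PULSE_DURATION_US = 150.0

# noise defaults: sigma on the absorbed fraction chosen so synthetic
# per-curve adjusted R^2 spans roughly the printed 0.34-0.85 range;
# fluorescence sigma in a.u. against an I0 = 100 amplitude
DEFAULT_SIGMA_RATIO = 0.03
DEFAULT_SIGMA_FLUOR = 2.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation, master seed, replicates."""

    sigma: float
    seed: int = 20191014
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not (self.sigma >= 0):
            raise ValidationError("sigma must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    def streams(self) -> list[np.random.Generator]:
        """One independent generator per replicate, derived from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(self.n_replicates)
        return [np.random.default_rng(c) for c in children]


@dataclass(frozen=True)
class TraceStageSpec:
    """Stage structure of an electrode trace.

    Stage I is a fast exponential surface-adsorption drop
    (``stage1_amplitude`` uM with time constant ``stage1_tau`` s); stage II
    a plateau of ``stage2_duration`` s before slow absorption starts.  A
    pulsed sample has no delay stage, so ``pef_applied`` requires
    ``stage2_duration == 0``.
    """

    stage1_amplitude: float = 0.15
    stage1_tau: float = 3.0
    stage2_duration: float = 240.0
    pef_applied: bool = False

    def __post_init__(self) -> None:
        if self.stage1_amplitude < 0:
            raise ValidationError("stage1_amplitude must be >= 0")
        if not (self.stage1_tau > 0):
            raise ValidationError("stage1_tau must be > 0 s")
        if self.stage2_duration < 0:
            raise ValidationError("stage2_duration must be >= 0 s")
        if self.pef_applied and self.stage2_duration != 0:
            raise ValidationError("pulsed traces have no delay stage: stage2_duration must be 0")


def generate_fluorescence_series(
    params: MembraneFluorescenceParams,
    delta_t_grid=None,
    noise: NoiseSpec = NoiseSpec(sigma=DEFAULT_SIGMA_FLUOR),
) -> list[FluorescenceSeries]:
    """Replicates of the fluorescence design: exact decay plus noise."""
    grid = np.asarray(
        DEFAULT_FLUOR_DELAYS if delta_t_grid is None else delta_t_grid, dtype=float
    )
    if grid.size == 0:
        raise ValidationError("delta_t_grid must be non-empty")
    clean = np.asarray(fluorescence_intensity(params, grid), dtype=float)
    out = []
    for i, rng in enumerate(noise.streams()):
        y = clean + rng.normal(0.0, noise.sigma, size=grid.shape) if noise.sigma > 0 else clean.copy()
        out.append(FluorescenceSeries(delta_t=grid, intensity=y, replicate_id=f"rep{i:03d}"))
    return out


def generate_uptake_dataset(
    constants: UptakeConstants,
    wall_by_field: dict,
    delta_t_grid=None,
    incubation_t: float = DEFAULT_INCUBATION_T,
    noise: NoiseSpec = NoiseSpec(sigma=DEFAULT_SIGMA_RATIO),
) -> list[UptakeRecoveryDataset]:
    """Replicates of the uptake-recovery design, one dataset per field.

    ``wall_by_field`` maps field strength (kV/cm) to the
    :class:`~pefreseal.params.WallPoreParams` acting at that field.  Noisy
    fractions are clipped to [0, 1] (means of ratios cannot leave the
    physical range).  Output is replicate-major, fields ascending.
    """
    grid = np.asarray(
        DEFAULT_UPTAKE_DELAYS if delta_t_grid is None else delta_t_grid, dtype=float
    )
    if grid.size == 0:
        raise ValidationError("delta_t_grid must be non-empty")
    fields = sorted(float(E) for E in wall_by_field)
    clean = {
        E: np.asarray(
            uptake_with_delay(constants, wall_by_field[E], incubation_t, grid),
            dtype=float,
        )
        for E in fields
    }
    out = []
    for i, rng in enumerate(noise.streams()):
        for E in fields:
            y = clean[E]
            if noise.sigma > 0:
                y = np.clip(y + rng.normal(0.0, noise.sigma, size=grid.shape), 0.0, 1.0)
            out.append(
                UptakeRecoveryDataset(
                    field_strength=E,
                    delta_t=grid,
                    ratio=y,
                    incubation_t=incubation_t,
                    replicate_id=f"rep{i:03d}",
                )
            )
    return out


def generate_electrode_trace(
    constants: UptakeConstants,
    wall: WallPoreParams,
    stages: TraceStageSpec,
    t_grid,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> np.ndarray:
    """Supernatant TPP+ concentration traces, shape (n_replicates, n_times).

    The trace starts at N_s + stage1_amplitude, drops by the fast
    surface-adsorption exponential, stays flat through the delay stage and
    then falls by the absorbed amount of the closed-form uptake solution
    (time shifted to the end of the delay stage).
    """
    grid = np.asarray(t_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValidationError("t_grid must be a 1-d array of times")
    if grid[0] < 0 or (grid.size > 1 and not np.all(np.diff(grid) > 0)):
        raise ValidationError("t_grid must be non-negative and strictly increasing")

    stage1 = stages.stage1_amplitude * (1.0 - np.exp(-grid / stages.stage1_tau))
    t_absorb = np.clip(grid - stages.stage2_duration, 0.0, None)
    absorbed = np.asarray(uptake_closed_form(constants, wall, t_absorb), dtype=float)
    clean = constants.N_s + stages.stage1_amplitude - stage1 - absorbed

    traces = np.empty((noise.n_replicates, grid.size))
    for i, rng in enumerate(noise.streams()):
        traces[i] = clean + (
            rng.normal(0.0, noise.sigma, size=grid.shape) if noise.sigma > 0 else 0.0
        )
    return traces
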