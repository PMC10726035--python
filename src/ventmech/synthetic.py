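"""Ventilator-like waveform generation with known ground truth.

Emulates the kind of records a pressure- or volume-controlled ventilator
produces — 150 s at 10 ms sampling by default, i.e. 15 000 rows of
(pressure, flow, volume), about 50 breathing cycles — so that every
estimator and simulator in the package can be exercised against data
whose generating model and parameters are known exactly.

Pressure-controlled (PC) mode: the pressure program is a periodic
trapezoid — baseline at PEEP (3 mbar), a linear rise to the plateau
(15 mbar) over the rise time, a hold through the inspiratory fraction of
the cycle, a linear fall back to PEEP — and volume is obtained by
forward simulation of the ground-truth model.  Volume-controlled (VC)
mode: constant inspiratory flow sized to deliver the tidal volume
(0.3 L), passive exponential expiration scaled so every cycle's net
volume is exactly zero, volume by integration of flow, and pressure from
the ground-truth model applied to (V, V').

In both modes the three stored channels are made mutually consistent
with the discretization conventions of the fitting pipeline (flow is the
backward difference of volume on the grid; pressure is the ground-truth
model evaluated on the stored volume and flow), after which independent
zero-mean Gaussian noise is added per channel — the flow channel gets
its own noise rather than being a derivative of the noisy volume,
mirroring a ventilator's independent flow sensor.  The noiseless record
and the true parameters are returned alongside.

The default ground truth is the single-compartment model at the
physiological porcine regime E = 26.1130 cmH2O/L, R = 7.1716 cmH2O*s/L,
P0 = 3.3972 mbar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import WaveformRecord
from .models import ModelSpec, build_design_matrix, get_spec
from .simulation import SimulationConfig, simulate_volume

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_pressure_program",
           "generate_flow_program", "generate_record", "DEFAULT_TRUTH_COEFFICIENTS"]

#: single-compartment truth (E, R, P0) used by default
DEFAULT_TRUTH_COEFFICIENTS = (26.1130, 7.1716, 3.3972)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ventilation program, ground truth and noise for one fixture.

    Units: pressures mbar, volumes L, times s, flows L/s.
    """

    mode: str = "PC"
    peep: float = 3.0
    plateau: float = 15.0
    peak: float = 16.0  # set-point metadata; the trapezoid tops out at the plateau
    tidal_volume: float = 0.3
    breath_period: float = 3.0
    insp_fraction: float = 0.33
    rise_time: float = 0.1
    duration: float = 150.0
    h: float = 0.01
    noise_sd_pressure: float = 0.05
    noise_sd_flow: float = 0.005
    noise_sd_volume: float = 0.001
    seed: int | None = 0
    truth_model: str = "single"
    truth_coefficients: tuple[float, ...] = DEFAULT_TRUTH_COEFFICIENTS
    truth_ncps: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("PC", "VC"):
            raise ValueError("mode must be 'PC' or 'VC'")
        if not (self.duration > 0 and self.breath_period > 0 and self.h > 0):
            raise ValueError("durations must be positive")
        if not (self.peep < self.plateau <= self.peak):
            raise ValueError("need PEEP < plateau <= peak")
        if not (self.tidal_volume > 0):
            raise ValueError("tidal volume must be positive")
        if not (0 < self.insp_fraction < 1):
            raise ValueError("inspiratory fraction must be in (0, 1)")
        if self.rise_time < 0 or self.rise_time > self.insp_fraction * self.breath_period:
            raise ValueError("rise time must fit inside the inspiratory phase")
        object.__setattr__(self, "truth_ncps", dict(self.truth_ncps))

    @property
    def n(self) -> int:
        return int(round(self.duration / self.h))

    @property
    def spec(self) -> ModelSpec:
        return get_spec(self.truth_model)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth bundle returned with every generated record."""

    record: WaveformRecord  # noiseless
    spec: ModelSpec
    coefficients: np.ndarray
    ncp_values: dict[str, float]
    config: SyntheticConfig


def _cycle_counts(config: SyntheticConfig) -> tuple[int, int, int]:
    n_cycle = int(round(config.breath_period / config.h))
    n_insp = int(round(config.insp_fraction * config.breath_period / config.h))
    n_rise = int(round(config.rise_time / config.h))
    if n_cycle < 2 or n_insp < 1 or n_insp >= n_cycle:
        raise ValueError("breath period too short for the sampling interval")
    return n_cycle, n_insp, n_rise


def generate_pressure_program(config: SyntheticConfig) -> np.ndarray:
    """Periodic trapezoid pressure for PC mode, length duration/h."""
    if config.mode != "PC":
        raise ValueError("pressure program is defined for PC mode")
    n_cycle, n_insp, n_rise = _cycle_counts(config)
    cycle = np.full(n_cycle, config.peep)
    ramp_up = (
        np.linspace(config.peep, config.plateau, n_rise, endpoint=False)
        if n_rise
        else np.empty(0)
    )
    cycle[:n_rise] = ramp_up
    cycle[n_rise:n_insp] = config.plateau
    n_fall = min(n_rise, n_cycle - n_insp)
    if n_fall:
        cycle[n_insp : n_insp + n_fall] = np.linspace(
            config.plateau, config.peep, n_fall, endpoint=False
        )
    n = config.n
    reps = -(-n // n_cycle)
    return np.tile(cycle, reps)[:n]


def generate_flow_program(config: SyntheticConfig) -> np.ndarray:
    """VC-mode flow: constant inspiration, exponential passive expiration.

    The discrete integral over each inspiration equals the tidal volume
    exactly, and the whole-cycle discrete integral is exactly zero, so
    the integrated volume returns to baseline every breath.
    """
    if config.mode != "VC":
        raise ValueError("flow program is defined for VC mode")
    n_cycle, n_insp, _ = _cycle_counts(config)
    n_exp = n_cycle - n_insp
    q_insp = config.tidal_volume / (n_insp * config.h)
    cycle = np.empty(n_cycle)
    cycle[:n_insp] = q_insp
    tau = max(n_exp * config.h / 5.0, config.h)  # passive decay constant
    shape = np.exp(-np.arange(n_exp) * config.h / tau)
    cycle[n_insp:] = -shape * (config.tidal_volume / (config.h * float(np.sum(shape))))
    n = config.n
    reps = -(-n // n_cycle)
    return np.tile(cycle, reps)[:n]


def generate_record(
    config: SyntheticConfig,
    sim_config: SimulationConfig | None = None,
) -> tuple[WaveformRecord, SyntheticTruth]:
    """Noisy record plus its noiseless ground truth.

    The noiseless channels satisfy the ground-truth model equation
    row-by-row under the package's discretization conventions, so a
    zero-noise fixture is recovered exactly by the estimator.
    """
    spec = config.spec
    A = np.asarray(config.truth_coefficients, dtype=float)
    if A.shape[0] != len(spec.terms):
        raise ValueError(
            f"truth model {spec.name!r} needs {len(spec.terms)} coefficients, "
            f"got {A.shape[0]}"
        )
    missing = set(spec.ncp_names) - set(config.truth_ncps)
    if missing:
        raise ValueError(f"truth model {spec.name!r} needs NCP values for {sorted(missing)}")
    h = config.h
    cfg = sim_config or SimulationConfig()

    if config.mode == "PC":
        program = generate_pressure_program(config)
        volume = simulate_volume(
            program, spec, A, config.truth_ncps, h=h, config=cfg
        )
        flow = np.empty_like(volume)
        flow[0] = volume[0] / h  # backward difference with zero pre-history
        flow[1:] = np.diff(volume) / h
    else:
        flow = generate_flow_program(config)
        volume = np.cumsum(flow) * h  # V[i] = V[i-1] + flow[i] h, V[-1] = 0
    clean = WaveformRecord(
        pressure=np.zeros_like(volume), flow=flow, volume=volume, h=h
    )
    # model-consistent pressure on the stored channels
    X = build_design_matrix(clean, spec, config.truth_ncps)
    pressure = X @ A
    clean = clean.with_channels(pressure=pressure)

    rng = np.random.default_rng(config.seed)
    noisy = WaveformRecord(
        pressure=pressure + rng.normal(0.0, config.noise_sd_pressure, clean.n)
        if config.noise_sd_pressure > 0
        else pressure.copy(),
        flow=flow + rng.normal(0.0, config.noise_sd_flow, clean.n)
        if config.noise_sd_flow > 0
        else flow.copy(),
        volume=volume + rng.normal(0.0, config.noise_sd_volume, clean.n)
        if config.noise_sd_volume > 0
        else volume.copy(),
        h=h,
    )
    truth = SyntheticTruth(
        record=clean,
        spec=spec,
        coefficients=A,
        ncp_values=dict(config.truth_ncps),
        config=config,
    )
    return noisy, truth
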