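"""Synthetic dual-wavelength PPG and temperature streams with known truth.

Stands in for the optical and thermometer hardware so the whole processing
chain is testable on a desk.  Each PPG channel is

    x(t) = DC * (1 + a * s(t)) + noise,

where s(t) is a unit peak-to-peak pulse waveform at the heart-beat
frequency and ``a`` is the channel's AC/DC ratio (its perfusion index,
measured peak-to-trough).  The infrared perfusion index is set directly;
the red one is scaled so that the ratio of ratios

    R = (AC/DC)_red / (AC/DC)_ir

equals the value the chosen calibration line maps to the requested SpO2.
The extraction chain therefore has an exact ground truth to recover.

The default pulse shape is a fundamental plus a 0.3-amplitude second
harmonic with a phase offset — a minimal caricature of the systolic
upstroke and dicrotic notch of a real PPG beat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.stats import truncnorm

from .errors import InvalidParameterError
from .vitals import (
    CalibrationLine,
    MAXIM,
    get_calibration,
    quantize_temperature,
)

#: second-harmonic relative amplitude and phase of the default pulse shape
SECOND_HARMONIC_AMPLITUDE = 0.3
SECOND_HARMONIC_PHASE = np.pi / 4


def default_pulse_shape(phase: np.ndarray) -> np.ndarray:
    """Two-harmonic pulse waveform evaluated at ``phase`` (cycles)."""
    return np.sin(2 * np.pi * phase) + SECOND_HARMONIC_AMPLITUDE * np.sin(
        4 * np.pi * phase + SECOND_HARMONIC_PHASE
    )


def _unit_ptp_shape(shape: Callable[[np.ndarray], np.ndarray]):
    """Rescale a periodic shape to zero mean and unit peak-to-peak."""
    grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
    ref = shape(grid)
    mean, ptp = ref.mean(), np.ptp(ref)
    if ptp == 0:
        raise InvalidParameterError("pulse shape has zero peak-to-peak range")

    def scaled(phase: np.ndarray) -> np.ndarray:
        return (shape(phase) - mean) / ptp

    return scaled


def ratio_for_spo2(spo2_percent: float, calibration: CalibrationLine) -> float:
    """Invert the calibration line: the R that yields ``spo2_percent``.

    Raises if the requested saturation is not attainable with a positive
    ratio on this line (e.g. 110% on the classic line).
    """
    r = (calibration.intercept - spo2_percent) / calibration.slope
    if r <= 0:
        raise InvalidParameterError(
            f"SpO2 {spo2_percent}% needs R = {r:.4g} <= 0 on the "
            f"{calibration.name!r} line; not attainable"
        )
    return r


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of one synthetic PPG window.

    dc_red / dc_ir are in arbitrary intensity units; perfusion_index_ir is
    the infrared AC/DC ratio (peak-to-trough over baseline), physiological
    fingertip values being a few percent.  noise_sd is the per-sample
    Gaussian noise SD applied identically to both channels.
    """

    heart_rate_bpm: float = 75.0
    spo2_percent: float = 97.0
    calibration: str = MAXIM.name
    dc_red: float = 0.9
    dc_ir: float = 1.0
    perfusion_index_ir: float = 0.05
    noise_sd: float = 0.0
    sampling_rate_hz: float = 100.0
    duration_s: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not 30.0 <= self.heart_rate_bpm <= 220.0:
            raise InvalidParameterError("heart_rate_bpm must be in [30, 220]")
        if self.sampling_rate_hz < 25.0:
            raise InvalidParameterError("sampling_rate_hz must be >= 25")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        if self.dc_red <= 0 or self.dc_ir <= 0:
            raise InvalidParameterError("DC levels must be positive")
        if not 0 < self.perfusion_index_ir <= 0.2:
            raise InvalidParameterError("perfusion_index_ir must be in (0, 0.2]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        # raises if the SpO2 is unattainable on this line
        ratio_for_spo2(self.spo2_percent, self.calibration_line)

    @property
    def calibration_line(self) -> CalibrationLine:
        return get_calibration(self.calibration)

    @property
    def truth_ratio(self) -> float:
        return ratio_for_spo2(self.spo2_percent, self.calibration_line)


@dataclass
class DualPPG:
    """Sampled red + infrared waveforms on a common time base."""

    sampling_rate_hz: float
    red: np.ndarray
    ir: np.ndarray
    truth: SimulationParams | None = None

    def __post_init__(self):
        self.red = np.asarray(self.red, dtype=float)
        self.ir = np.asarray(self.ir, dtype=float)
        if self.red.shape != self.ir.shape or self.red.size < 2:
            raise InvalidParameterError(
                "red and ir must have equal length >= 2"
            )
        if not (np.all(np.isfinite(self.red)) and np.all(np.isfinite(self.ir))):
            raise InvalidParameterError("all samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.red.size / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.red.size) / self.sampling_rate_hz

    def scaled(self, factor: float) -> "DualPPG":
        """Both channels multiplied by a common positive constant."""
        if factor <= 0:
            raise InvalidParameterError("scale factor must be positive")
        return DualPPG(self.sampling_rate_hz, self.red * factor,
                       self.ir * factor, truth=self.truth)


def synthesize_ppg(
    params: SimulationParams,
    shape: Callable[[np.ndarray], np.ndarray] = default_pulse_shape,
) -> DualPPG:
    """Generate one dual-wavelength PPG window from ground-truth parameters.

    Deterministic for a given ``params`` (the seed drives a dedicated
    generator; no global RNG state is touched).
    """
    unit = _unit_ptp_shape(shape)
    n = int(round(params.duration_s * params.sampling_rate_hz))
    t = np.arange(n) / params.sampling_rate_hz
    phase = params.heart_rate_bpm / 60.0 * t
    s = unit(phase)

    pi_ir = params.perfusion_index_ir
    pi_red = params.truth_ratio * pi_ir
    rng = np.random.default_rng(params.seed)
    red = params.dc_red * (1.0 + pi_red * s)
    ir = params.dc_ir * (1.0 + pi_ir * s)
    if params.noise_sd > 0:
        red = red + rng.normal(0.0, params.noise_sd, n)
        ir = ir + rng.normal(0.0, params.noise_sd, n)
    return DualPPG(params.sampling_rate_hz, red, ir, truth=params)


def synthesize_temperature(
    true_temp_c: float,
    accuracy_bound_c: float = 0.5,
    resolution_c: float = 0.0625,
    n: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Thermometer readings: bounded sensor error, then grid quantization.

    The datasheet of the emulated part gives only an accuracy bound
    (+/-0.5 degC) and a resolution (0.0625 degC in 12-bit mode), so the
    error model is a truncated Gaussian with SD = bound/2, truncated at
    +/-bound, and every reading is snapped to the resolution grid.
    """
    if resolution_c <= 0:
        raise InvalidParameterError("resolution_c must be positive")
    if accuracy_bound_c < 0:
        raise InvalidParameterError("accuracy_bound_c must be non-negative")
    if n < 1:
        raise InvalidParameterError("n must be at least 1")
    if accuracy_bound_c == 0:
        errors = np.zeros(n)
    else:
        sd = accuracy_bound_c / 2.0
        rng = np.random.default_rng(seed)
        errors = truncnorm.rvs(-2.0, 2.0, scale=sd, size=n, random_state=rng)
    return quantize_temperature(true_temp_c + errors, resolution_c)


def with_seed(params: SimulationParams, seed: int) -> SimulationParams:
    """Convenience: same scenario, different random draw."""
    return replace(params, seed=seed)
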