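"""Patient-layer signal processing for a dual-wavelength pulse oximeter.

Turns raw red/infrared photoplethysmography (PPG) waveforms and a raw
thermometer reading into one vital-sign record:

* heart rate from the median interval between detected PPG peaks,
* SpO2 from the ratio of ratios R = (AC/DC)_red / (AC/DC)_ir pushed through
  an empirical linear calibration SpO2% = intercept - slope * R,
* body temperature quantized to the sensor's resolution grid (the DS18B20
  thermometer reports multiples of 0.0625 degC in 12-bit mode).

The AC amplitude convention is peak-to-trough (peak-to-peak) of the
pulsatile component; the same convention is used by the simulator, so it
cancels in R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, TYPE_CHECKING

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .errors import (
    InsufficientSignalError,
    InvalidParameterError,
    InvalidSignalError,
    StageError,
    UndefinedRatioError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import DualPPG

DEFAULT_MIN_HR_BPM = 30.0
DEFAULT_MAX_HR_BPM = 220.0
#: DS18B20 12-bit resolution, degrees Celsius.
TEMP_RESOLUTION_C = 0.0625
#: Fraction of the pulsatile peak-to-peak range a peak must rise above.
PEAK_PROMINENCE_FRACTION = 0.3
#: Width of the short smoothing window applied before peak picking, seconds.
PEAK_SMOOTH_S = 0.05


# --------------------------------------------------------------------------
# calibration lines
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationLine:
    """Empirical linear map from the ratio of ratios R to SpO2 percent.

    SpO2% = intercept - slope * R.  Two presets are provided: the textbook
    approximation 110 - 25R and the Maxim Integrated device calibration
    104 - 17R (the MAX30102 sensor is a Maxim part, hence the default
    elsewhere in the package).
    """

    name: str
    intercept: float
    slope: float

    def __post_init__(self):
        if self.slope <= 0 or self.intercept <= 0:
            raise InvalidParameterError(
                "calibration slope and intercept must be positive"
            )

    def spo2(self, r: float) -> float:
        """Raw (unclamped) SpO2 percent for ratio ``r``."""
        return self.intercept - self.slope * r


CLASSIC = CalibrationLine("classic", 110.0, 25.0)
MAXIM = CalibrationLine("maxim", 104.0, 17.0)
CALIBRATION_PRESETS = {c.name: c for c in (CLASSIC, MAXIM)}


def get_calibration(name: str) -> CalibrationLine:
    try:
        return CALIBRATION_PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown calibration preset {name!r}; "
            f"available: {sorted(CALIBRATION_PRESETS)}"
        ) from None


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class PeakTrain:
    """Detected PPG peak times in seconds over a window of known duration."""

    peak_times: np.ndarray
    source_duration: float
    flag: str | None = None  # e.g. "no pulsatile activity"

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size:
            if np.any(np.diff(self.peak_times) <= 0):
                raise InvalidParameterError("peak times must be strictly increasing")
            if self.peak_times[0] < 0 or self.peak_times[-1] > self.source_duration:
                raise InvalidParameterError("peak times outside the source window")

    def __len__(self) -> int:
        return int(self.peak_times.size)


@dataclass
class PPGComponents:
    """Per-channel AC (peak-to-trough) and DC (baseline) amplitudes."""

    ac_red: float
    dc_red: float
    ac_ir: float
    dc_ir: float

    def __post_init__(self):
        if self.dc_red <= 0 or self.dc_ir <= 0:
            raise InvalidSignalError("DC levels must be positive")
        if self.ac_red < 0 or self.ac_ir < 0:
            raise InvalidSignalError("AC amplitudes must be non-negative")


class SpO2Estimate(NamedTuple):
    """Calibrated SpO2 with the clamping flag and pre-clamp value."""

    percent: float
    clamped: bool
    raw_percent: float


class HeartRateCategory(str, Enum):
    BELOW_NORMAL = "below_normal"
    NORMAL = "normal"
    ABOVE_NORMAL = "above_normal"


@dataclass
class VitalRecord:
    """One timestamped measurement: the unit of telemetry."""

    heart_rate_bpm: float
    spo2_percent: float
    temperature_c: float
    timestamp: float
    subject_id: str

    def __post_init__(self):
        if not 0 <= self.spo2_percent <= 100:
            raise InvalidParameterError("spo2_percent must be in [0, 100]")
        if self.heart_rate_bpm <= 0:
            raise InvalidParameterError("heart_rate_bpm must be positive")


# --------------------------------------------------------------------------
# heart rate
# --------------------------------------------------------------------------

def _baseline(x: np.ndarray, fs: float, min_hr_bpm: float) -> np.ndarray:
    """Moving-average baseline over twice the longest admissible beat."""
    w = int(round(2 * (60.0 / min_hr_bpm) * fs))
    w = max(1, min(w, x.size))
    return uniform_filter1d(x, size=w, mode="reflect")


def detect_peaks(
    channel: np.ndarray,
    sampling_rate_hz: float,
    min_hr_bpm: float = DEFAULT_MIN_HR_BPM,
    max_hr_bpm: float = DEFAULT_MAX_HR_BPM,
) -> PeakTrain:
    """Locate systolic peaks in one PPG channel.

    Local maxima of the baseline-removed, lightly smoothed signal, separated
    by at least one minimal beat period (60/max_hr) and with prominence above
    an adaptive threshold (a fixed fraction of the window's pulsatile
    peak-to-peak range).  A flat window yields an empty train flagged
    "no pulsatile activity" rather than an error.
    """
    if not 0 < min_hr_bpm < max_hr_bpm:
        raise InvalidParameterError("need 0 < min_hr_bpm < max_hr_bpm")
    x = np.asarray(channel, dtype=float)
    duration = x.size / sampling_rate_hz
    if duration < 2.0:
        raise InsufficientSignalError("need at least 2 s of signal")
    if np.ptp(x) == 0.0:
        return PeakTrain(np.empty(0), duration, flag="no pulsatile activity")

    pulsatile = x - _baseline(x, sampling_rate_hz, min_hr_bpm)
    smooth_w = max(1, int(round(PEAK_SMOOTH_S * sampling_rate_hz)))
    pulsatile = uniform_filter1d(pulsatile, size=smooth_w, mode="reflect")
    rng = np.ptp(pulsatile)
    if rng == 0.0:
        return PeakTrain(np.empty(0), duration, flag="no pulsatile activity")

    distance = max(2, int(round(sampling_rate_hz * 60.0 / max_hr_bpm)))
    # reflect-pad by one longest beat so a peak close to either boundary
    # keeps its full prominence instead of being cut by the window edge
    pad = min(x.size - 1, int(round(sampling_rate_hz * 60.0 / min_hr_bpm)))
    padded = np.concatenate((pulsatile[pad:0:-1], pulsatile, pulsatile[-2:-pad - 2:-1]))
    idx, _ = find_peaks(
        padded, distance=distance, prominence=PEAK_PROMINENCE_FRACTION * rng
    )
    # keep in-range peaks; the first/last samples themselves can only be
    # maxima as mirror artifacts, so they are excluded
    idx = idx[(idx > pad) & (idx < pad + x.size - 1)]
    times = (idx - pad) / sampling_rate_hz
    if idx.size >= 3:
        # refine each peak to sub-sample accuracy by a local quadratic
        # least-squares fit over a quarter-beat window; without this, peak
        # times are quantized to the sample grid (alone a ~2 bpm error at
        # fast heart rates) and on a flat-topped pulse the raw argmax
        # jitters by tens of milliseconds under additive noise
        period = float(np.median(np.diff(idx))) / sampling_rate_hz
        times = _refine_peak_times(padded, sampling_rate_hz, idx, period) - pad / sampling_rate_hz
        keep = np.concatenate(([True], np.diff(times) > 0))
        times = times[keep]
        times = times[(times >= 0) & (times <= duration)]
    return PeakTrain(times, duration)


def _refine_peak_times(
    pulsatile: np.ndarray, fs: float, idx: np.ndarray, period_s: float
) -> np.ndarray:
    """Quadratic least-squares vertex refinement of detected peak indices."""
    h = max(2, int(round(0.25 * period_s * fs)))
    times = np.empty(idx.size)
    for j, i in enumerate(idx):
        a, b = max(0, i - h), min(pulsatile.size, i + h + 1)
        xs = np.arange(a, b, dtype=float) - i
        c2, c1, _ = np.polyfit(xs, pulsatile[a:b], 2)
        delta = -c1 / (2 * c2) if c2 < 0 else 0.0
        delta = float(np.clip(delta, -0.4 * period_s * fs, 0.4 * period_s * fs))
        times[j] = (i + delta) / fs
    return times


def beat_frequency(
    channel: np.ndarray,
    sampling_rate_hz: float,
    min_hr_bpm: float = DEFAULT_MIN_HR_BPM,
    max_hr_bpm: float = DEFAULT_MAX_HR_BPM,
) -> float:
    """Fundamental beat frequency (Hz) of one PPG channel, spectrally.

    Coarse pick of the dominant rFFT bin inside the admissible band, then a
    bounded local search maximizing the sinusoidal projection amplitude.
    Unlike peak-interval estimates this does not care about occasional
    missed beats, and over a multi-beat window it resolves the frequency to
    a small fraction of a bin — which matters because harmonic regression
    (see ``extract_components``) needs end-to-end phase coherence.
    """
    x = np.asarray(channel, dtype=float)
    pulsatile = x - _baseline(x, sampling_rate_hz, min_hr_bpm)
    if np.ptp(pulsatile) == 0:
        raise InsufficientSignalError("no pulsatile activity")
    n = pulsatile.size
    windowed = pulsatile * np.hanning(n)
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate_hz)
    spectrum = np.abs(np.fft.rfft(windowed))
    band = (freqs >= min_hr_bpm / 60.0) & (freqs <= max_hr_bpm / 60.0)
    if not band.any():
        raise InsufficientSignalError("window too short to resolve the beat band")
    spectrum[~band] = 0.0
    f_coarse = freqs[int(np.argmax(spectrum))]

    t = np.arange(n) / sampling_rate_hz

    def neg_amplitude(f: float) -> float:
        return -float(
            np.hypot(
                pulsatile @ np.cos(2 * np.pi * f * t),
                pulsatile @ np.sin(2 * np.pi * f * t),
            )
        )

    df = sampling_rate_hz / n
    res = minimize_scalar(
        neg_amplitude,
        bounds=(f_coarse - 1.5 * df, f_coarse + 1.5 * df),
        method="bounded",
    )
    return float(res.x)


def heart_rate_from_peaks(peaks: PeakTrain) -> float:
    """Heart rate in bpm as 60 / median inter-peak interval.

    The median makes a single missed or spurious beat inert: intervals
    {0.8, 0.8, 2.0} still give 75 bpm, not 50.
    """
    if len(peaks) < 2:
        raise InsufficientSignalError(
            "need at least 2 peaks to estimate heart rate"
            + (f" ({peaks.flag})" if peaks.flag else "")
        )
    return 60.0 / float(np.median(np.diff(peaks.peak_times)))


def classify_heart_rate(hr_bpm: float) -> HeartRateCategory:
    """Resting-adult bucket; 60 and 100 bpm are both inside 'normal'."""
    if hr_bpm <= 0:
        raise InvalidParameterError("heart rate must be positive")
    if hr_bpm < 60.0:
        return HeartRateCategory.BELOW_NORMAL
    if hr_bpm > 100.0:
        return HeartRateCategory.ABOVE_NORMAL
    return HeartRateCategory.NORMAL


# --------------------------------------------------------------------------
# SpO2 chain
# --------------------------------------------------------------------------

def _harmonic_ptp(
    pulsatile: np.ndarray, fs: float, f0: float, n_harmonics: int = 2
) -> float:
    """Peak-to-trough of the harmonic-regression fit at beat frequency f0.

    Least-squares projection onto sin/cos pairs at f0, 2*f0, ... is linear in
    the data, so white noise averages out over the window instead of
    inflating the extremes the way a direct max-min over noisy samples does.
    """
    t = np.arange(pulsatile.size) / fs
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * k * f0 * t))
        cols.append(np.cos(2 * np.pi * k * f0 * t))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, pulsatile, rcond=None)
    fitted = design[:, 1:] @ coef[1:]  # drop the constant: AC only
    return float(np.ptp(fitted))


def _per_beat_ptp(pulsatile: np.ndarray, fs: float, peaks: PeakTrain) -> float:
    """Median peak-to-trough amplitude across detected beats."""
    idx = np.round(peaks.peak_times * fs).astype(int)
    amps = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = pulsatile[a : b + 1]
        amps.append(0.5 * (pulsatile[a] + pulsatile[b]) - seg.min())
    return float(np.median(amps))


def extract_components(
    ppg: "DualPPG",
    min_hr_bpm: float = DEFAULT_MIN_HR_BPM,
    max_hr_bpm: float = DEFAULT_MAX_HR_BPM,
    method: str = "harmonic",
) -> PPGComponents:
    """Split each channel into DC baseline and AC pulsatile amplitude.

    DC is the mean of a moving-average baseline (window = twice the longest
    admissible beat).  AC is the peak-to-trough amplitude of the pulsatile
    remainder, estimated either by harmonic regression at the detected beat
    frequency (``method="harmonic"``, the default — robust to additive
    noise) or as the median per-beat peak-to-trough (``method="per_beat"``).
    Beat timing is taken from the infrared channel, which carries the
    stronger pulsatile signal on a reflective oximeter; the red channel
    falls back as reference if the infrared one shows no beats.
    """
    if method not in ("harmonic", "per_beat"):
        raise InvalidParameterError(f"unknown AC estimation method {method!r}")
    fs = ppg.sampling_rate_hz
    channels = {"red": np.asarray(ppg.red, float), "ir": np.asarray(ppg.ir, float)}
    if channels["ir"].size / fs < 2.0:
        raise InsufficientSignalError("need at least 2 s of signal")

    dc, pulsatile = {}, {}
    for name, x in channels.items():
        base = _baseline(x, fs, min_hr_bpm)
        dc[name] = float(base.mean())
        if dc[name] <= 0:
            raise InvalidSignalError(f"non-positive DC level on {name} channel")
        pulsatile[name] = x - base

    # beat timing from the stronger channel
    ref_peaks = detect_peaks(channels["ir"], fs, min_hr_bpm, max_hr_bpm)
    if len(ref_peaks) < 2:
        ref_peaks = detect_peaks(channels["red"], fs, min_hr_bpm, max_hr_bpm)
    if len(ref_peaks) < 2:
        # no pulsatile activity anywhere: both AC amplitudes are zero
        return PPGComponents(0.0, dc["red"], 0.0, dc["ir"])

    ac = {}
    if method == "harmonic":
        ref_name = "ir" if np.ptp(pulsatile["ir"]) > 0 else "red"
        f0 = beat_frequency(channels[ref_name], fs, min_hr_bpm, max_hr_bpm)
        # drop half a baseline window at each end: the moving average is
        # edge-distorted there and would shrink the fitted amplitude
        n = next(iter(pulsatile.values())).size
        w = int(round(2 * (60.0 / min_hr_bpm) * fs))
        trim = min(w // 2, n // 4)
        sl = slice(trim, n - trim)
        for name in channels:
            ac[name] = _harmonic_ptp(pulsatile[name][sl], fs, f0)
    else:
        for name in channels:
            own = detect_peaks(channels[name], fs, min_hr_bpm, max_hr_bpm)
            peaks = own if len(own) >= 2 else ref_peaks
            ac[name] = max(0.0, _per_beat_ptp(pulsatile[name], fs, peaks))
    return PPGComponents(ac["red"], dc["red"], ac["ir"], dc["ir"])


def compute_ratio(c: PPGComponents) -> float:
    """Ratio of ratios R = (AC/DC)_red / (AC/DC)_ir."""
    if c.ac_ir == 0:
        raise UndefinedRatioError("infrared AC amplitude is zero; R undefined")
    return (c.ac_red / c.dc_red) / (c.ac_ir / c.dc_ir)


def spo2_from_ratio(r: float, calibration: CalibrationLine) -> SpO2Estimate:
    """Apply a calibration line and clamp to the physical range [0, 100].

    Clamping is flagged instead of raised: the linear approximations exceed
    100% for small R, but saturation is physically bounded.
    """
    if r < 0:
        raise InvalidParameterError("ratio R must be non-negative")
    raw = calibration.spo2(r)
    clamped = not 0.0 <= raw <= 100.0
    return SpO2Estimate(float(np.clip(raw, 0.0, 100.0)), clamped, raw)


def spo2_definition(hbo2: float, hb: float) -> float:
    """Definition of saturation: oxygenated over total hemoglobin, percent."""
    if hbo2 < 0 or hb < 0:
        raise InvalidParameterError("hemoglobin amounts must be non-negative")
    if hbo2 + hb == 0:
        raise InvalidParameterError("total hemoglobin is zero; SpO2 undefined")
    return 100.0 * hbo2 / (hbo2 + hb)


# --------------------------------------------------------------------------
# temperature
# --------------------------------------------------------------------------

def quantize_temperature(temp_c: float, resolution_c: float = TEMP_RESOLUTION_C) -> float:
    """Snap to the nearest multiple of the sensor resolution.

    Ties round away from zero (36.6875 + half a step goes up, not to even).
    """
    if resolution_c <= 0:
        raise InvalidParameterError("resolution must be positive")
    t = np.asarray(temp_c, dtype=float)
    q = np.sign(t) * np.floor(np.abs(t) / resolution_c + 0.5) * resolution_c
    return float(q) if np.isscalar(temp_c) or q.ndim == 0 else q


# --------------------------------------------------------------------------
# composed window processor
# --------------------------------------------------------------------------

def process_window(
    ppg: "DualPPG",
    temp_c: float,
    calibration: CalibrationLine = MAXIM,
    subject_id: str = "anon",
    timestamp: float = 0.0,
    temp_resolution_c: float = TEMP_RESOLUTION_C,
) -> VitalRecord:
    """One window of raw signal -> one VitalRecord.

    Composes peak detection -> heart rate, component extraction -> R ->
    calibrated SpO2, and temperature quantization.  A failure in any stage
    is re-raised as a StageError naming the stage.
    """
    try:
        peaks = detect_peaks(np.asarray(ppg.ir, float), ppg.sampling_rate_hz)
        hr = heart_rate_from_peaks(peaks)
    except Exception as exc:  # noqa: BLE001 - tag and rethrow
        raise StageError("heart_rate", str(exc)) from exc
    try:
        comp = extract_components(ppg)
        spo2 = spo2_from_ratio(compute_ratio(comp), calibration)
    except Exception as exc:  # noqa: BLE001
        raise StageError("spo2", str(exc)) from exc
    try:
        temp = quantize_temperature(temp_c, temp_resolution_c)
    except Exception as exc:  # noqa: BLE001
        raise StageError("temperature", str(exc)) from exc
    return VitalRecord(
        heart_rate_bpm=hr,
        spo2_percent=spo2.percent,
        temperature_c=temp,
        timestamp=timestamp,
        subject_id=subject_id,
    )
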