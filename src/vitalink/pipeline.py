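"""End-to-end patient -> cloud -> clinician pipeline on synthetic data.

simulate -> extract -> encrypt -> store -> decrypt -> compare-to-truth,
writing every intermediate artifact plus a structured stage log.  All
randomness flows from the single seed in the RunConfig (split into
independent streams for the waveform and the IVs), so a run is
reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .errors import StageError, VitalinkError
from .securelink import SecretKey, decrypt_record, encrypt_record, serialize_record
from .securelink import InMemoryCipherStore
from .simulate import SimulationParams, synthesize_ppg, synthesize_temperature
from .vitals import get_calibration, process_window


@dataclass
class RunConfig:
    """Everything one pipeline invocation depends on."""

    seed: int
    key_file: str
    output_dir: str
    calibration: str = "maxim"
    heart_rate_bpm: float = 75.0
    spo2_percent: float = 97.0
    temperature_c: float = 36.6
    noise_sd: float = 0.0
    sampling_rate_hz: float = 100.0
    duration_s: float = 30.0
    send_period_s: float = 5.0
    subject_id: str = "sim-001"

    def __post_init__(self):
        if self.send_period_s <= 0:
            raise VitalinkError("send_period_s must be positive")


@dataclass
class PipelineResult:
    truth: SimulationParams
    delivered: "object"  # VitalRecord
    hr_error_bpm: float
    spo2_error_pp: float
    artifacts: dict[str, Path]
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the five-step flow once and write artifacts under output_dir."""
    key_path = Path(config.key_file)
    if not key_path.exists():
        raise StageError("config", f"key file not found: {key_path}")
    key = vio.read_key_file(key_path)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    artifacts: dict[str, Path] = {}
    clock = 0.0

    def note(stage: str, message: str) -> None:
        log.append(f"t={clock:07.2f}s [{stage}] {message}")

    # independent child seeds for the waveform, the thermometer and the IV
    seq = np.random.SeedSequence(config.seed)
    sim_seed, temp_seed, iv_seed = (int(s.generate_state(1)[0] % 2**31)
                                    for s in seq.spawn(3))

    params = SimulationParams(
        heart_rate_bpm=config.heart_rate_bpm,
        spo2_percent=config.spo2_percent,
        calibration=config.calibration,
        noise_sd=config.noise_sd,
        sampling_rate_hz=config.sampling_rate_hz,
        duration_s=config.duration_s,
        seed=sim_seed,
    )
    try:
        ppg = synthesize_ppg(params)
    except VitalinkError as exc:
        raise StageError("simulate", str(exc)) from exc
    artifacts["ppg"] = outdir / "ppg.csv"
    vio.write_ppg_csv(ppg, artifacts["ppg"])
    note("simulate", f"hr={params.heart_rate_bpm} spo2={params.spo2_percent} "
                     f"noise_sd={params.noise_sd} seed={sim_seed}")

    temp_reading = float(
        synthesize_temperature(config.temperature_c, n=1, seed=temp_seed)[0]
    )
    note("simulate", f"temperature reading {temp_reading}")

    record = process_window(
        ppg,
        temp_reading,
        calibration=get_calibration(config.calibration),
        subject_id=config.subject_id,
        timestamp=clock,
    )
    artifacts["record"] = outdir / "record.json"
    artifacts["record"].write_text(vio.record_to_json(record), encoding="utf-8")
    note("extract", f"hr={record.heart_rate_bpm:.2f} "
                    f"spo2={record.spo2_percent:.2f} temp={record.temperature_c}")

    iv = np.random.default_rng(iv_seed).integers(0, 256, 16, dtype=np.uint8).tobytes()
    enc = encrypt_record(serialize_record(record), key, iv)
    store = InMemoryCipherStore()
    clock += config.send_period_s
    store.put(f"records/{config.subject_id}/0", enc)
    artifacts["payload"] = outdir / "payload.b64"
    artifacts["payload"].write_text(
        f"{enc.key_id}\n{enc.iv.hex()}\n{enc.ciphertext_b64}\n", encoding="utf-8"
    )
    note("encrypt", f"key_id={enc.key_id} iv={enc.iv.hex()} "
                    f"ct_len={len(enc.ciphertext())}")

    fetched = store.get(f"records/{config.subject_id}/0")
    try:
        delivered = decrypt_record(fetched, key)
    except VitalinkError as exc:
        raise StageError("decrypt", str(exc)) from exc
    artifacts["delivered"] = outdir / "delivered.json"
    artifacts["delivered"].write_text(vio.record_to_json(delivered), encoding="utf-8")
    note("decrypt", "record delivered")

    hr_err = abs(delivered.heart_rate_bpm - config.heart_rate_bpm)
    spo2_err = abs(delivered.spo2_percent - config.spo2_percent)
    note("validate", f"|hr error|={hr_err:.3f} bpm, |spo2 error|={spo2_err:.3f} pp")

    artifacts["log"] = outdir / "pipeline.log"
    artifacts["log"].write_text("\n".join(log) + "\n", encoding="utf-8")
    return PipelineResult(params, delivered, hr_err, spo2_err, artifacts, log)
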