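"""File formats: waveform CSV, ground-truth sidecar, key files, record JSON.

Waveforms travel as a two-column (red, ir) CSV whose first line is a
comment carrying the sampling rate; an optional sidecar of key = value
lines preserves the simulation ground truth.  Keys are one line of 32 hex
characters.  All text is UTF-8, comma-separated, dot decimal.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PayloadFormatError
from .securelink import SecretKey
from .simulate import DualPPG, SimulationParams
from .vitals import VitalRecord


def write_ppg_csv(ppg: DualPPG, path, truth_sidecar: bool = True) -> None:
    """Write a waveform; ground truth (if any) goes to ``<path>.truth``."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sampling_rate_hz={ppg.sampling_rate_hz!r}\n")
        fh.write("red,ir\n")
        for r, i in zip(ppg.red, ppg.ir):
            fh.write(f"{float(r)!r},{float(i)!r}\n")
    if truth_sidecar and ppg.truth is not None:
        write_truth_sidecar(ppg.truth, path.with_suffix(path.suffix + ".truth"))


def read_ppg_csv(path) -> DualPPG:
    """Read a waveform written by :func:`write_ppg_csv`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("# sampling_rate_hz="):
            raise PayloadFormatError(
                f"{path}: first line must carry '# sampling_rate_hz=...'"
            )
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != ["red", "ir"]:
        raise PayloadFormatError(f"{path}: expected columns red,ir")
    truth = None
    sidecar = path.with_suffix(path.suffix + ".truth")
    if sidecar.exists():
        truth = read_truth_sidecar(sidecar)
    return DualPPG(fs, df["red"].to_numpy(), df["ir"].to_numpy(), truth=truth)


def write_truth_sidecar(params: SimulationParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in dataclasses.asdict(params).items():
            fh.write(f"{key} = {value!r}\n")


def read_truth_sidecar(path) -> SimulationParams:
    fields = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition(" = ")
            fields[key] = value
    kwargs = {}
    for f in dataclasses.fields(SimulationParams):
        raw = fields[f.name]
        if f.name == "calibration":
            kwargs[f.name] = raw.strip("'\"")
        elif f.name == "seed":
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = float(raw)
    return SimulationParams(**kwargs)


def read_key_file(path, key_id: str | None = None) -> SecretKey:
    """One line of 32 hex characters; key id defaults to the file stem."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    return SecretKey.from_hex(text, key_id or path.stem)


def write_key_file(key: SecretKey, path) -> None:
    Path(path).write_text(key.key_bytes.hex() + "\n", encoding="utf-8")


def record_to_json(rec: VitalRecord) -> str:
    return json.dumps(
        {
            "subject_id": rec.subject_id,
            "timestamp": rec.timestamp,
            "hr": rec.heart_rate_bpm,
            "spo2": rec.spo2_percent,
            "temp": rec.temperature_c,
        },
        indent=2,
        sort_keys=True,
    )


def record_from_json(text: str) -> VitalRecord:
    try:
        obj = json.loads(text)
        return VitalRecord(
            heart_rate_bpm=obj["hr"],
            spo2_percent=obj["spo2"],
            temperature_c=obj["temp"],
            timestamp=obj["timestamp"],
            subject_id=obj["subject_id"],
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise PayloadFormatError(f"invalid record JSON: {exc}") from exc
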