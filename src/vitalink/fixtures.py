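"""Packaged paired-reading tables from the device validation study.

Three CSV tables of measured-versus-reference readings, taken from 20
individuals with commercial devices as the reference: 50 heart-rate pairs,
50 SpO2 pairs and 40 body-temperature pairs.  Each row carries the reading
number, the device-under-test value, the commercial reference value, and
the percent error as printed in the source tables (used to cross-check
the recomputed error column).

Files are hash-checked at load so a corrupted installation fails loudly
rather than producing silently wrong agreement statistics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .agreement import PairedReadings
from .errors import CorruptedFixtureError, InvalidParameterError

_FIXTURES = {
    "hr": ("hr_pairs.csv", "heart_rate", 50),
    "spo2": ("spo2_pairs.csv", "spo2", 50),
    "temp": ("temperature_pairs.csv", "temperature", 40),
}

_SHA256 = {
    "hr_pairs.csv": "1c32b73c88a24248d573756a8167df857867cc659272cc69018637171b94a22e",
    "spo2_pairs.csv": "31198745a576d6e7e75d192eab12eb913500125cbc881b81d165cd70eb9ea44a",
    "temperature_pairs.csv": "4fe56793cc14d25e16bae271b0608e4bb31fa6fd3216d73db8533f8c93aa5637",
}

FIXTURE_NAMES = tuple(_FIXTURES)


@dataclass
class FixtureTable:
    """A loaded reference table plus its printed per-reading errors."""

    name: str
    pairs: PairedReadings
    printed_error_pct: np.ndarray


def load_fixture(name: str) -> FixtureTable:
    """Load one packaged table ('hr', 'spo2' or 'temp'), integrity-checked."""
    try:
        filename, parameter, expected_rows = _FIXTURES[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        ) from None
    ref = resources.files("vitalink.data").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _SHA256[filename]:
        raise CorruptedFixtureError(
            f"{filename}: sha256 {digest} != expected {_SHA256[filename]}"
        )
    with ref.open("r") as fh:
        df = pd.read_csv(fh)
    if list(df.columns) != ["reading_no", "measured", "reference", "error_pct"]:
        raise CorruptedFixtureError(f"{filename}: unexpected columns {list(df.columns)}")
    if len(df) != expected_rows:
        raise CorruptedFixtureError(
            f"{filename}: expected {expected_rows} rows, got {len(df)}"
        )
    pairs = PairedReadings(
        parameter, df["measured"].to_numpy(), df["reference"].to_numpy()
    )
    return FixtureTable(name, pairs, df["error_pct"].to_numpy(dtype=float))
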