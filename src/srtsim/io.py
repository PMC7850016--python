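"""WAV and tabular I/O helpers.

WAV files are written as 32-bit float RIFF so sample values round-trip
exactly. Result tables use CSV with a documented, stable column schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = ["write_wav", "read_wav", "write_results", "read_results"]

#: Column schema of the tidy per-trial results table.
TRIALS_SCHEMA = {
    "listener": str,
    "condition": str,
    "reversed": bool,
    "run": int,
    "trial": int,
    "snr_db": float,
    "correct": bool,
    "is_reversal": bool,
}

#: Column schema of the per-condition summary table.
SUMMARY_SCHEMA = {
    "listener": str,
    "condition": str,
    "reversed": bool,
    "srt_db": float,
    "n_runs": int,
    "n_discarded": int,
}


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    """Write a waveform as float32 PCM (lossless round trip for float32)."""
    wavfile.write(str(path), sample_rate, np.asarray(samples, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file to float64 samples in [-1, 1] plus its sample rate."""
    sample_rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64), int(sample_rate)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as CSV with deterministic row order."""
    table.to_csv(path, index=False)


def read_results(path: str | Path, schema: dict | None = None) -> pd.DataFrame:
    """Read a results CSV back, coercing to the given column schema."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed results CSV {path}: {exc}") from exc
    if schema:
        missing = set(schema) - set(table.columns)
        if missing:
            raise ValueError(f"results CSV {path} missing columns {sorted(missing)}")
        for col, typ in schema.items():
            table[col] = table[col].astype(typ)
    return table
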