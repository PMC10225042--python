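"""Audio and tabular I/O for the cough-analysis pipeline.

Recordings are mono WAV files (the study protocol records at 44.1 kHz, but any
positive rate is accepted and propagated — every downstream feature is defined
per second or per frame, so no resampling is performed).  Cohort metadata maps
each file to a subject, a maneuver class, a microphone channel, and an
induction method.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

MANEUVER_CLASSES = ("voluntary_cough", "throat_clearing", "reflexive_cough")
MICROPHONES = ("free_standing", "skin_contact")
INDUCTION_METHODS = ("none", "urge_to_cough", "suppressed")

#: Column order of a cohort metadata table.
COHORT_COLUMNS = ("file_id", "subject", "maneuver", "microphone", "induction", "token")


@dataclass(frozen=True)
class Waveform:
    """A sampled mono signal.

    Parameters
    ----------
    samples : ndarray
        1-D float array of dimensionless amplitudes.
    rate : float
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"waveform must be mono (1-D); got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("waveform must contain at least one sample")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive; got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


# Full-scale divisor per integer WAV encoding: divide by 2^(bits-1), the
# asymmetric full-scale convention (so -full-scale maps to exactly -1.0).
_INT_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,  # scipy returns 24-bit PCM zero-padded in int32
}


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a single-channel WAV file.

    Integer encodings (PCM-16/24/32, unsigned 8-bit) are scaled to [-1, 1] by
    dividing by 2^(bits-1); float encodings are passed through unchanged.

    Raises
    ------
    ValueError
        If the file holds more than one channel (the error names the channel
        count) or uses an unsupported sample encoding.
    """
    rate, data = wavfile.read(os.fspath(path))
    if data.ndim > 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample encoding {data.dtype}")
    return Waveform(samples=samples, rate=float(rate))


def write_wav(path: str | os.PathLike, w: Waveform, encoding: str = "float32") -> None:
    """Write a waveform as a mono RIFF WAV file.

    ``encoding`` is one of ``pcm16``, ``pcm32``, ``float32``, ``float64``.
    ``float64`` round-trips bit-exactly through :func:`read_wav`; integer
    encodings round-trip within one quantization step.
    """
    x = w.samples
    if encoding == "pcm16":
        data = np.clip(np.round(x * 2.0**15), -(2.0**15), 2.0**15 - 1).astype(np.int16)
    elif encoding == "pcm32":
        data = np.clip(np.round(x * 2.0**31), -(2.0**31), 2.0**31 - 1).astype(np.int32)
    elif encoding == "float32":
        data = x.astype(np.float32)
    elif encoding == "float64":
        data = x.astype(np.float64)
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")
    wavfile.write(os.fspath(path), int(round(w.rate)), data)


def make_cohort_table(rows) -> pd.DataFrame:
    """Build and validate a cohort metadata table.

    ``rows`` is an iterable of mappings with the keys in :data:`COHORT_COLUMNS`.
    """
    df = pd.DataFrame(list(rows), columns=list(COHORT_COLUMNS))
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Check enumeration membership and key uniqueness of a cohort table."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad_class = set(df["maneuver"]) - set(MANEUVER_CLASSES)
    if bad_class:
        raise ValueError(f"unknown maneuver class values: {sorted(bad_class)}")
    bad_mic = set(df["microphone"]) - set(MICROPHONES)
    if bad_mic:
        raise ValueError(f"unknown microphone values: {sorted(bad_mic)}")
    bad_ind = set(df["induction"]) - set(INDUCTION_METHODS)
    if bad_ind:
        raise ValueError(f"unknown induction values: {sorted(bad_ind)}")
    key = ["subject", "maneuver", "microphone", "token"]
    if df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)]
        raise ValueError(
            "duplicate (subject, maneuver, microphone, token) keys:\n"
            + dupes[key].to_string(index=False)
        )


def write_feature_table(records, path: str | os.PathLike, columns=None) -> None:
    """Write per-segment feature rows to CSV with a stable column order.

    All records must share one schema (same keys, same order); ``columns``
    supplies the schema explicitly (required to get a header-only CSV from an
    empty record list).  Values round-trip through :func:`read_feature_table`
    to better than 1e-12 relative error (17 significant digits are written).
    """
    records = list(records)
    if records:
        schema = list(records[0].keys())
        if columns is not None and list(columns) != schema:
            raise ValueError(f"records do not match declared columns {list(columns)}")
        for i, rec in enumerate(records):
            if list(rec.keys()) != schema:
                raise ValueError(
                    f"record {i} schema {list(rec.keys())} differs from first "
                    f"record schema {schema}"
                )
        df = pd.DataFrame(records, columns=schema)
    else:
        df = pd.DataFrame(columns=list(columns) if columns is not None else [])
    df.to_csv(os.fspath(path), index=False, float_format="%.17g")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_feature_table`."""
    return pd.read_csv(os.fspath(path))
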