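"""File formats: WAV stimuli, JSON impulse-train sidecars, EDF EEG, HDF5 responses.

EEG interchange uses EDF (16-bit integers with physical scaling), written
by a small built-in writer and read back through :mod:`mne`, so simulated
recordings and real recordings share a single reader path.  Response
waveforms are stored losslessly in HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .response_extraction import ResponseWaveform
from .stimulus import ImpulseTrain

__all__ = [
    "write_wav",
    "read_wav",
    "train_to_json",
    "train_from_json",
    "write_edf",
    "read_edf",
    "save_responses",
    "load_responses",
]


def write_wav(path: str | Path, samples: np.ndarray, fs_hz: float) -> Path:
    """Write a stimulus token as 32-bit float WAV."""
    from scipy.io import wavfile

    path = Path(path)
    wavfile.write(path, int(round(fs_hz)), np.asarray(samples, dtype=np.float32))
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    return np.asarray(data, dtype=float), float(fs)


def train_to_json(train: ImpulseTrain, path: str | Path, frequency_hz: float | None = None) -> Path:
    """Write an impulse train (timing + polarity metadata) as a JSON sidecar."""
    path = Path(path)
    payload = {
        "frequency_hz": frequency_hz,
        "indices": train.indices.tolist(),
        "polarities": train.polarities.tolist(),
        "rate_per_s": train.rate_per_s,
        "duration_s": train.duration_s,
        "sample_rate_hz": train.sample_rate_hz,
        "seed": train.seed,
    }
    path.write_text(json.dumps(payload))
    return path


def train_from_json(path: str | Path) -> tuple[ImpulseTrain, float | None]:
    d = json.loads(Path(path).read_text())
    train = ImpulseTrain(
        indices=np.asarray(d["indices"], dtype=np.int64),
        polarities=np.asarray(d["polarities"], dtype=np.int8),
        rate_per_s=d["rate_per_s"],
        duration_s=d["duration_s"],
        sample_rate_hz=d["sample_rate_hz"],
        seed=d["seed"],
    )
    return train, d.get("frequency_hz")


def _edf_field(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    fs_hz: float,
    channel_labels: list[str] | None = None,
) -> Path:
    """Write EEG as a plain EDF file (16-bit, physical units microvolts).

    ``samples`` is in volts, shape ``(n,)`` or ``(n_channels, n)``.  Data
    are split into 1 s records; the final partial record is zero-padded,
    so recordings are stored rounded up to whole seconds.  Readable by any
    EDF reader (mne.io.read_raw_edf is used in :func:`read_edf`).
    """
    path = Path(path)
    x = np.atleast_2d(np.asarray(samples, dtype=float)) * 1e6  # to microvolts
    n_ch, n = x.shape
    labels = channel_labels or [f"EEG{i + 1}" for i in range(n_ch)]
    spr = int(round(fs_hz))  # samples per 1 s record
    n_rec = int(np.ceil(n / spr))
    pad = n_rec * spr - n
    if pad:
        x = np.hstack([x, np.zeros((n_ch, pad))])

    phys_max = max(float(np.max(np.abs(x))), 1e-6) * 1.000001
    phys_max = float(f"{phys_max:.6g}")  # match the 8-char header field exactly
    dig_min, dig_max = -32768, 32767
    # EDF two-point calibration: value = phys_min + (digital - dig_min) * slope
    slope = 2.0 * phys_max / (dig_max - dig_min)
    digital = np.clip(
        np.round((x + phys_max) / slope) + dig_min, dig_min, dig_max
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(1, 8),
            _edf_field(n_ch, 4),
        ]
    )
    fmt = lambda v: f"{v:.6g}"
    signal_header = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in labels),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in labels),
            b"".join(_edf_field("uV", 8) for _ in labels),
            b"".join(_edf_field(fmt(-phys_max), 8) for _ in labels),
            b"".join(_edf_field(fmt(phys_max), 8) for _ in labels),
            b"".join(_edf_field(dig_min, 8) for _ in labels),
            b"".join(_edf_field(dig_max, 8) for _ in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field(spr, 8) for _ in labels),
            b"".join(_edf_field("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + signal_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an EDF recording; returns (samples in volts, sampling rate)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])


def save_responses(path: str | Path, responses: list[ResponseWaveform]) -> Path:
    """Store response waveforms (and condition metadata) in one HDF5 file."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        for i, r in enumerate(responses):
            g = fh.create_group(f"response_{i:04d}")
            g.create_dataset("w", data=r.w)
            g.attrs["fs_hz"] = r.fs_hz
            g.attrs["lag_start_s"] = r.lag_start_s
            g.attrs["n_stimuli"] = r.n_stimuli
            g.attrs["condition"] = json.dumps(r.condition)
    return path


def load_responses(path: str | Path) -> list[ResponseWaveform]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            g = fh[key]
            out.append(
                ResponseWaveform(
                    w=np.asarray(g["w"]),
                    fs_hz=float(g.attrs["fs_hz"]),
                    lag_start_s=float(g.attrs["lag_start_s"]),
                    n_stimuli=int(g.attrs["n_stimuli"]),
                    condition=json.loads(g.attrs["condition"]),
                )
            )
    return out
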