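"""European Data Format (EDF) reading and writing for the 16-channel montage.

Reading goes through ``mne.io.read_raw_edf`` and canonicalizes channel
labels against the montage. Writing is a minimal standard-conformant EDF
implementation (ASCII header, one-second int16 data records, physical
dimension uV) — deliberately small, validated by round-tripping through the
mne reader.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .montage import CHANNELS, canonicalize_channel
from .recording import RawRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path: str | Path) -> Path:
    """Write a recording as EDF with 1 s data records.

    Requires an integer sampling rate and a whole number of seconds of
    data. The start date/time fields are fixed (01.01.2000), so the output
    bytes are deterministic for identical inputs.
    """
    path = Path(path)
    data = recording.data
    if not np.isfinite(data).all():
        raise ValueError("cannot write non-finite samples to EDF")
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = data.shape
    if n_samp % fs:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = n_samp // fs

    # symmetric physical range per channel, headroom against clipping
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-3)
    phys_max = np.array([float(f"{v * 1.0001:.4g}") for v in phys_max])
    scale = (_DIG_MAX - _DIG_MIN) / (2 * phys_max)
    digital = np.clip(
        np.rint((data + phys_max[:, None]) * scale[:, None]) + _DIG_MIN,
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field(recording.subject_id or "X", 80),
        _field(recording.session or "X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_ch + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(label, 16) for label in recording.channel_names),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(f"{-m:.4g}", 8) for m in phys_max),
        b"".join(_field(f"{m:.4g}", 8) for m in phys_max),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_edf(
    path: str | Path, subject_id: str = "", session: str = ""
) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (data in uV).

    Channel labels are canonicalized case-insensitively against the
    16-channel montage; missing or unexpected labels raise with the
    offending names listed. Subject/session default to the
    ``<subject>_<session>.edf`` filename convention when not given.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    mapping: dict[str, str] = {}
    unknown: list[str] = []
    for name in raw.ch_names:
        canon = canonicalize_channel(name)
        if canon is None:
            unknown.append(name)
        else:
            mapping[canon] = name
    missing = [c for c in CHANNELS if c not in mapping]
    if missing or unknown:
        raise ValueError(
            f"channel mismatch in {path.name}: missing {missing or 'none'}, "
            f"unrecognized {unknown or 'none'}"
        )
    data_v = raw.get_data(picks=[mapping[c] for c in CHANNELS])
    if not (subject_id and session):
        parts = path.stem.split("_")
        subject_id = subject_id or parts[0]
        session = session or (parts[1] if len(parts) > 1 else "")
    return RawRecording(
        data=data_v * 1e6,  # mne returns SI volts
        channel_names=CHANNELS,
        sample_rate=float(raw.info["sfreq"]),
        subject_id=subject_id,
        session=session,
    )


# ---------------------------------------------------------------------------
# Dataset directories: EDF files + a sidecar label manifest


def write_dataset(recordings: list[RawRecording], out_dir: str | Path) -> Path:
    """One EDF per recording plus ``manifest.csv`` (subject, session, class)."""
    from .synth import LABEL_CODES

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "session", "class", "file"])
        for rec in recordings:
            fname = f"{rec.subject_id}_{rec.session}.edf"
            write_edf(rec, out_dir / fname)
            writer.writerow(
                [rec.subject_id, rec.session, LABEL_CODES.get(rec.session, ""), fname]
            )
    return manifest


def read_dataset(in_dir: str | Path) -> list[RawRecording]:
    """Read every recording listed in a directory's ``manifest.csv``."""
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {in_dir}")
    recordings = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            recordings.append(
                read_edf(in_dir / row["file"], row["subject_id"], row["session"])
            )
    return recordings
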