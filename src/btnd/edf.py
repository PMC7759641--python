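"""EDF reading and writing for seizure recordings.

Reading goes through MNE's EDF reader.  Writing uses a minimal built-in
16-bit EDF encoder (one-second data records, per-channel physical
scaling), sufficient for round-tripping synthetic recordings through the
command-line pipeline.
"""

from __future__ import annotations

import datetime
import re
from pathlib import Path

import numpy as np

from .types import SeizureRecording


def read_recording(
    path: str | Path,
    channel_pattern: str | None = None,
    channels: list[str] | None = None,
) -> SeizureRecording:
    """Load an EDF file as a :class:`~btnd.types.SeizureRecording` (microvolts).

    ``channel_pattern`` selects channels by regex; ``channels`` selects an
    explicit list (missing names raise, naming every absent channel).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if channels is not None:
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ValueError(f"channels not in file: {missing}")
        picks = channels
    elif channel_pattern is not None:
        rx = re.compile(channel_pattern)
        picks = [c for c in labels if rx.search(c)]
    else:
        picks = labels
    if not picks:
        raise ValueError("channel selection is empty")
    raw.pick(picks)
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:  # pragma: no cover - mne enforces a single sfreq
        raise ValueError(f"mixed sampling rates: {sorted(sfreqs)}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return SeizureRecording(
        samples=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        seizure_id=Path(path).stem,
    )


def _ascii_field(value: str, width: int) -> bytes:
    out = value.encode("ascii", errors="replace")[:width]
    return out.ljust(width)


def write_edf(recording: SeizureRecording, path: str | Path) -> None:
    """Write a recording (microvolts) as a standard 16-bit EDF file.

    Uses one-second data records, so the sampling rate must be an integer
    and trailing samples beyond the last whole second are dropped.
    """
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    nchan = recording.n_channels
    data = recording.samples[:, : n_records * fs]

    pmaxs = np.maximum(np.abs(data).max(axis=1), 1.0)
    dmin, dmax = -32768, 32767
    digital = np.empty_like(data, dtype=np.int16)
    for c in range(nchan):
        scaled = (data[c] + pmaxs[c]) / (2 * pmaxs[c]) * (dmax - dmin) + dmin
        digital[c] = np.round(scaled).astype(np.int16)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(recording.seizure_id or "X", 80),
            _ascii_field("Startdate 01-JAN-2000", 80),
            _ascii_field(now.strftime("%d.%m.%y"), 8),
            _ascii_field(now.strftime("%H.%M.%S"), 8),
            _ascii_field(str(256 * (1 + nchan)), 8),
            _ascii_field("", 44),
            _ascii_field(str(n_records), 8),
            _ascii_field("1", 8),
            _ascii_field(str(nchan), 4),
        ]
    )
    fields = [
        (recording.channel_labels, 16),
        (["" for _ in range(nchan)], 80),            # transducer
        (["uV"] * nchan, 8),                         # physical dimension
        ([f"{-p:.6g}"[:8] for p in pmaxs], 8),       # physical min
        ([f"{p:.6g}"[:8] for p in pmaxs], 8),        # physical max
        ([str(dmin)] * nchan, 8),
        ([str(dmax)] * nchan, 8),
        (["" for _ in range(nchan)], 80),            # prefiltering
        ([str(fs)] * nchan, 8),                      # samples per record
        (["" for _ in range(nchan)], 32),
    ]
    signal_header = b"".join(
        b"".join(_ascii_field(v, width) for v in values)
        for values, width in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.astype("<i2").tobytes())
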