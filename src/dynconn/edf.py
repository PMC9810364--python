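"""Minimal EDF (European Data Format) reader/writer.

Implements just enough of the EDF specification for round-tripping
multichannel recordings: fixed 256-byte global header, per-signal header
fields, and 16-bit little-endian samples scaled between the digital and
physical ranges.  Written files use 1-second data records when the sampling
rate is integral and the duration is a whole number of seconds, otherwise a
single record covering the whole signal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .connectivity import EegRecording

__all__ = ["write_edf", "read_edf", "read_edf_header", "read_text_recording",
           "write_text_recording"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _fmt(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width and isinstance(value, float):
        for prec in range(width - 2, 0, -1):  # widest %g that fits
            s = f"{value:.{prec}g}"
            if len(s) <= width:
                break
    if len(s) > width:
        raise ValueError(f"value {value!r} does not fit in {width} EDF chars")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: EegRecording,
              patient_id: str = "X", recording_id: str = "synthetic") -> Path:
    """Write a recording as EDF with per-channel physical scaling."""
    path = Path(path)
    data = recording.data
    n_ch, n_samp = data.shape
    rate = recording.rate
    if float(rate).is_integer() and n_samp % int(rate) == 0:
        record_dur = 1.0
        spr = int(rate)
    else:
        record_dur = n_samp / rate
        spr = n_samp
    n_records = n_samp // spr
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    # digitize against the header-encoded (8-char) range, not the exact one,
    # so reading the file back inverts the scaling to within quantization
    phys_min = np.floor(phys_min * 1e3) / 1e3
    phys_max = np.ceil(phys_max * 1e3) / 1e3
    phys_min = np.asarray([float(_fmt(float(v), 8).decode()) for v in phys_min])
    phys_max = np.asarray([float(_fmt(float(v), 8).decode()) for v in phys_max])
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join([
        _fmt("0", 8),
        _fmt(patient_id, 80),
        _fmt(recording_id, 80),
        _fmt("01.01.00", 8),
        _fmt("00.00.00", 8),
        _fmt(256 * (n_ch + 1), 8),
        _fmt("", 44),
        _fmt(n_records, 8),
        _fmt(record_dur if record_dur != int(record_dur) else int(record_dur), 8),
        _fmt(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_fmt(lab, 16) for lab in recording.labels),
        b"".join(_fmt("", 80) for _ in range(n_ch)),           # transducer
        b"".join(_fmt("uV", 8) for _ in range(n_ch)),
        b"".join(_fmt(float(v), 8) for v in phys_min),
        b"".join(_fmt(float(v), 8) for v in phys_max),
        b"".join(_fmt(_DIG_MIN, 8) for _ in range(n_ch)),
        b"".join(_fmt(_DIG_MAX, 8) for _ in range(n_ch)),
        b"".join(_fmt("", 80) for _ in range(n_ch)),           # prefiltering
        b"".join(_fmt(spr, 8) for _ in range(n_ch)),
        b"".join(_fmt("", 32) for _ in range(n_ch)),
    ])
    body = bytearray()
    for r in range(n_records):
        chunk = digital[:, r * spr:(r + 1) * spr]
        body += chunk.tobytes()  # channel-major within a record, as per EDF
    path.write_bytes(header + sig + bytes(body))
    return path


def read_edf_header(path: str | Path) -> dict:
    """Parse the EDF global and per-signal headers (no sample data)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: too short to be an EDF file")

    def _s(lo, hi):
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    n_ch = int(_s(252, 256))
    header_bytes = int(_s(184, 192))
    if header_bytes != 256 * (n_ch + 1):
        raise ValueError(f"{path}: inconsistent EDF header size field")
    n_records = int(_s(236, 244))
    record_dur = float(_s(244, 252))
    off = 256

    def _field(width):
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width]
                .decode("ascii", errors="replace").strip() for i in range(n_ch)]
        off += width * n_ch
        return vals

    labels = _field(16)
    _field(80)  # transducer
    units = _field(8)
    phys_min = [float(v) for v in _field(8)]
    phys_max = [float(v) for v in _field(8)]
    dig_min = [int(v) for v in _field(8)]
    dig_max = [int(v) for v in _field(8)]
    _field(80)  # prefiltering
    spr = [int(v) for v in _field(8)]
    _field(32)
    if record_dur <= 0:
        raise ValueError(f"{path}: non-positive data record duration")
    return {
        "n_channels": n_ch,
        "n_records": n_records,
        "record_duration": record_dur,
        "labels": labels,
        "units": units,
        "physical_min": phys_min,
        "physical_max": phys_max,
        "digital_min": dig_min,
        "digital_max": dig_max,
        "samples_per_record": spr,
        "rate": spr[0] / record_dur if spr else 0.0,
        "data_offset": header_bytes,
    }


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF file back into physical units."""
    hdr = read_edf_header(path)
    raw = Path(path).read_bytes()
    n_ch = hdr["n_channels"]
    spr = hdr["samples_per_record"]
    if len(set(spr)) != 1:
        raise ValueError(f"{path}: mixed per-signal sampling rates unsupported")
    spr0 = spr[0]
    n_rec = hdr["n_records"]
    body = np.frombuffer(raw, dtype="<i2", offset=hdr["data_offset"],
                         count=n_ch * spr0 * n_rec)
    body = body.reshape(n_rec, n_ch, spr0)
    digital = np.concatenate([body[r] for r in range(n_rec)], axis=1).astype(float)
    pmin = np.asarray(hdr["physical_min"])[:, None]
    pmax = np.asarray(hdr["physical_max"])[:, None]
    dmin = np.asarray(hdr["digital_min"], float)[:, None]
    dmax = np.asarray(hdr["digital_max"], float)[:, None]
    data = (digital - dmin) * (pmax - pmin) / (dmax - dmin) + pmin
    return EegRecording(tuple(hdr["labels"]), hdr["rate"], data)


def write_text_recording(path: str | Path, recording: EegRecording) -> Path:
    """Delimited-text fallback: header row of labels, one column per channel;
    the sampling rate lives in a ``# rate=`` comment on the first line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={recording.rate}\n")
        fh.write("\t".join(recording.labels) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.8g", delimiter="\t")
    return path


def read_text_recording(path: str | Path, rate: float | None = None) -> EegRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("# rate="):
            rate = float(first.split("=", 1)[1])
            labels = fh.readline().strip().split("\t")
        else:
            if rate is None:
                raise ValueError(
                    f"{path}: no '# rate=' comment; pass rate explicitly"
                )
            labels = first.split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return EegRecording(tuple(labels), rate, data.T)
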