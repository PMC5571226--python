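"""Minimal WFDB (PhysioNet) record I/O.

Supports the subset needed for MIT-BIH-style beat records: a ``.hea``
header, a format-16 ``.dat`` signal file (interleaved little-endian
int16) and a ``.atr`` beat-annotation file in the MIT annotation format
(10-bit time increments with SKIP escapes).  Amplitudes are quantized by
the ADC gain (default 200 adu/mV), so signal round-trips are exact only
to 1/gain mV.

Annotation codes are mapped to the five AAMI classes; unknown beat codes
map to Q.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .beats import AAMI, BeatAnnotation, EcgRecord

# MIT annotation codes for beat types (subset)
_CODE_TO_AAMI = {
    1: AAMI.N,   # NORMAL
    2: AAMI.N,   # LBBB
    3: AAMI.N,   # RBBB
    4: AAMI.S,   # ABERR (aberrated atrial premature)
    5: AAMI.V,   # PVC
    6: AAMI.F,   # FUSION (of ventricular and normal)
    7: AAMI.S,   # NPC (nodal premature)
    8: AAMI.S,   # APC (atrial premature)
    9: AAMI.S,   # SVPB
    10: AAMI.V,  # VESC (ventricular escape)
    11: AAMI.N,  # NESC (nodal escape)
    12: AAMI.Q,  # PACE (paced)
    13: AAMI.Q,  # UNKNOWN
    34: AAMI.N,  # AESC (atrial escape)
    38: AAMI.Q,  # PFUS (fusion of paced and normal)
}
_AAMI_TO_CODE = {AAMI.N: 1, AAMI.S: 8, AAMI.V: 5, AAMI.F: 6, AAMI.Q: 13}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63
_MAX_BEAT_CODE = 49


def write_record(record: EcgRecord, directory, gain: float = 200.0) -> str:
    """Write ``<subject_id>.hea/.dat/.atr`` into ``directory``.

    Returns the record path (without extension).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.subject_id
    n = len(record.signal)
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    header = (
        f"{name} 1 {record.fs:g} {n}\n"
        f"{name}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0]) if n else 0} 0 0 MLII\n"
    )
    (directory / f"{name}.hea").write_text(header)
    _write_annotations(record.annotations, directory / f"{name}.atr")
    return str(directory / name)


def _write_annotations(annotations, path) -> None:
    out = bytearray()
    prev = 0
    for a in annotations:
        diff = a.r_sample - prev
        code = _AAMI_TO_CODE[a.label]
        if diff > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (diff >> 16) & 0xFFFF)
            out += struct.pack("<H", diff & 0xFFFF)
            diff = 0
        out += struct.pack("<H", (code << 10) | diff)
        prev = a.r_sample
    out += struct.pack("<H", 0)  # end of annotations
    Path(path).write_bytes(bytes(out))


def _read_annotations(path) -> list[BeatAnnotation]:
    data = Path(path).read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            if pending_skip >= 1 << 31:
                pending_skip -= 1 << 32
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)
            continue
        t += interval + pending_skip
        pending_skip = 0
        if code <= _MAX_BEAT_CODE:
            anns.append(BeatAnnotation(t, _CODE_TO_AAMI.get(code, AAMI.Q)))
    return anns


def read_record(record_path, channel: int = 0,
                subject_id: Optional[str] = None) -> EcgRecord:
    """Read a WFDB record given its path without extension.

    ``channel`` selects the signal (default: first, the modified-lead-II
    channel in MIT-BIH-style records).
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    try:
        lines = [
            ln for ln in hea.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        rec_fields = lines[0].split()
        name, nsig = rec_fields[0], int(rec_fields[1])
        fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
        sig_specs = [ln.split() for ln in lines[1:1 + nsig]]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed WFDB header {hea}: {exc}") from exc
    if not 0 <= channel < nsig:
        raise ValueError(f"channel {channel} out of range for {nsig} signals")
    spec = sig_specs[channel]
    fmt = spec[1].split("x")[0]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    gain_field = spec[2] if len(spec) > 2 else "200"
    gain_str = gain_field.split("/")[0]
    if "(" in gain_str:
        gain_str, baseline_str = gain_str.rstrip(")").split("(")
        baseline = float(baseline_str)
    else:
        baseline = float(spec[4]) if len(spec) > 4 else 0.0
    gain = float(gain_str) or 200.0

    raw = np.frombuffer(record_path.with_suffix(".dat").read_bytes(), dtype="<i2")
    signal = (raw.reshape(-1, nsig)[:, channel] - baseline) / gain

    atr = record_path.with_suffix(".atr")
    annotations = _read_annotations(atr) if atr.exists() else []
    return EcgRecord(
        subject_id=subject_id or name,
        signal=signal.astype(float),
        fs=fs,
        annotations=annotations,
    )
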