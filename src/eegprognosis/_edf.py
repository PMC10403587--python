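"""Minimal EDF / EDF+C reader and writer.

Implements the subset of the European Data Format the pipeline needs:
16-bit signals in microvolts with 1-second data records, plus the EDF+
annotation channel (timestamped annotation lists) for the technologist
events. Physical ranges are set per channel from the observed min/max
padded by 5%; out-of-range samples are clipped with a logged count.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

import numpy as np

from .containers import Annotation, Recording

logger = logging.getLogger(__name__)


class EDFFormatError(ValueError):
    """Raised when a file violates the EDF layout; names the byte offset."""


_HEADER_LEN = 256
_SIG_HEADER_LEN = 256
_ANN_LABEL = "EDF Annotations"


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def _num(value, width: int) -> bytes:
    for precision in range(10, 0, -1):
        text = f"{value:.{precision}g}"
        if len(text) <= width:
            return _field(text, width)
    return _field(f"{value:.0e}", width)


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as EDF (EDF+C when annotations exist)."""
    path = Path(path)
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate (1-s records)")
    n_ch, n_samp = recording.signal.shape
    n_records = math.ceil(n_samp / spr)
    sig = recording.signal
    if n_records * spr != n_samp:
        pad = n_records * spr - n_samp
        logger.warning("write_edf: padding last record with %d repeated samples", pad)
        sig = np.hstack([sig, np.repeat(sig[:, -1:], pad, axis=1)])

    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    span = phys_max - phys_min
    pad = np.where(span > 0, 0.05 * span, 1.0)
    phys_min = phys_min - pad
    phys_max = phys_max + pad
    dig_min, dig_max = -32768, 32767

    has_ann = len(recording.annotations) > 0
    ann_records: list[bytes] = []
    if has_ann:
        per_record: list[list[bytes]] = [[] for _ in range(n_records)]
        for ann in sorted(recording.annotations, key=lambda a: a.onset_s):
            rec_idx = min(int(ann.onset_s // 1.0), n_records - 1)
            tal = f"+{ann.onset_s:.4g}\x15{ann.duration_s:.4g}\x14{ann.label}\x14\x00"
            per_record[rec_idx].append(tal.encode("utf-8"))
        for rec_idx in range(n_records):
            stamp = f"+{rec_idx}\x14\x14\x00".encode("ascii")
            ann_records.append(stamp + b"".join(per_record[rec_idx]))
        ann_bytes = max(len(b) for b in ann_records)
        ann_spr = (ann_bytes + 1) // 2 + 1  # samples are 2 bytes; keep headroom
    n_signals = n_ch + (1 if has_ann else 0)

    header = b""
    header += _field("0", 8)
    header += _field(recording.patient_id, 80)
    header += _field(recording.eeg_id, 80)
    header += _field("01.01.20", 8)
    header += _field("00.00.00", 8)
    header += _num(_HEADER_LEN + n_signals * _SIG_HEADER_LEN, 8)
    header += _field("EDF+C" if has_ann else "", 44)
    header += _num(n_records, 8)
    header += _num(1, 8)
    header += _num(n_signals, 4)

    labels = list(recording.channel_labels) + ([_ANN_LABEL] if has_ann else [])
    sprs = [spr] * n_ch + ([ann_spr] if has_ann else [])
    pmins = list(phys_min) + ([-1.0] if has_ann else [])
    pmaxs = list(phys_max) + ([1.0] if has_ann else [])

    def sig_fields(fmt, width):
        return b"".join(_field(fmt(i), width) for i in range(n_signals))

    header += sig_fields(lambda i: labels[i], 16)
    header += sig_fields(lambda i: "", 80)  # transducer
    header += sig_fields(lambda i: "uV" if i < n_ch else "", 8)
    header += b"".join(_num(pmins[i], 8) for i in range(n_signals))
    header += b"".join(_num(pmaxs[i], 8) for i in range(n_signals))
    header += b"".join(_num(dig_min, 8) for _ in range(n_signals))
    header += b"".join(_num(dig_max, 8) for _ in range(n_signals))
    header += sig_fields(lambda i: "", 80)  # prefiltering
    header += b"".join(_num(sprs[i], 8) for i in range(n_signals))
    header += sig_fields(lambda i: "", 32)  # reserved

    # re-read the rounded physical ranges so scaling matches the header text
    pmins_r = [float(_num(pmins[i], 8).decode()) for i in range(n_signals)]
    pmaxs_r = [float(_num(pmaxs[i], 8).decode()) for i in range(n_signals)]

    n_clipped = 0
    digital = np.empty((n_ch, n_records * spr), dtype="<i2")
    for ci in range(n_ch):
        lo, hi = pmins_r[ci], pmaxs_r[ci]
        scale = (hi - lo) / (dig_max - dig_min)
        clipped = np.clip(sig[ci], lo, hi)
        n_clipped += int(np.count_nonzero((sig[ci] < lo) | (sig[ci] > hi)))
        digital[ci] = np.round((clipped - lo) / scale + dig_min).astype("<i2")
    if n_clipped:
        logger.warning("write_edf: clipped %d out-of-range samples", n_clipped)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_idx in range(n_records):
            sl = slice(rec_idx * spr, (rec_idx + 1) * spr)
            for ci in range(n_ch):
                fh.write(digital[ci, sl].tobytes())
            if has_ann:
                buf = ann_records[rec_idx].ljust(ann_spr * 2, b"\x00")
                fh.write(buf)


def _parse_float(raw: bytes, offset: int, what: str) -> float:
    try:
        return float(raw.decode("ascii").strip())
    except ValueError as exc:
        raise EDFFormatError(
            f"malformed header at byte {offset}: cannot parse {what} "
            f"from {raw!r}"
        ) from exc


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (signals in uV)."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < _HEADER_LEN:
        raise EDFFormatError(
            f"malformed header at byte 0: file has only {len(data)} bytes "
            f"(need {_HEADER_LEN})"
        )
    patient_id = data[8:88].decode("ascii", errors="replace").strip()
    eeg_id = data[88:168].decode("ascii", errors="replace").strip()
    n_records = int(_parse_float(data[236:244], 236, "number of data records"))
    record_dur = _parse_float(data[244:252], 244, "record duration")
    n_signals = int(_parse_float(data[252:256], 252, "number of signals"))
    if n_signals <= 0:
        raise EDFFormatError(f"malformed header at byte 252: {n_signals} signals")

    sig_hdr_end = _HEADER_LEN + n_signals * _SIG_HEADER_LEN
    if len(data) < sig_hdr_end:
        raise EDFFormatError(
            f"malformed header at byte {_HEADER_LEN}: signal headers truncated"
        )

    def sig_field(block: int, width: int, idx: int) -> tuple[bytes, int]:
        start = _HEADER_LEN + block + idx * width
        return data[start : start + width], start

    offsets = np.cumsum([0, 16, 80, 8, 8, 8, 8, 8, 80, 8]) * n_signals
    labels, pmin, pmax, dmin, dmax, spr = [], [], [], [], [], []
    for i in range(n_signals):
        labels.append(sig_field(offsets[0], 16, i)[0].decode("ascii").strip())
        pmin.append(_parse_float(*sig_field(offsets[3], 8, i), "physical minimum"))
        pmax.append(_parse_float(*sig_field(offsets[4], 8, i), "physical maximum"))
        dmin.append(_parse_float(*sig_field(offsets[5], 8, i), "digital minimum"))
        dmax.append(_parse_float(*sig_field(offsets[6], 8, i), "digital maximum"))
        spr.append(int(_parse_float(*sig_field(offsets[8], 8, i), "samples per record")))

    record_bytes = 2 * sum(spr)
    payload = len(data) - sig_hdr_end
    actual_records = payload // record_bytes if record_bytes else 0
    if n_records < 0:
        n_records = actual_records
    if actual_records < n_records or payload % record_bytes:
        raise EDFFormatError(
            f"truncated file: header declares {n_records} data records but the "
            f"payload holds {payload / record_bytes:.2f}"
        )

    is_ann = [lab == _ANN_LABEL for lab in labels]
    eeg_idx = [i for i in range(n_signals) if not is_ann[i]]
    raw = np.frombuffer(
        data, dtype="<i2", offset=sig_hdr_end, count=n_records * record_bytes // 2
    )
    signals = [np.empty(n_records * spr[i], dtype=np.float64) for i in eeg_idx]
    ann_chunks: list[bytes] = []
    pos = 0
    starts = np.cumsum([0] + spr)
    for rec_idx in range(n_records):
        rec = raw[pos : pos + record_bytes // 2]
        pos += record_bytes // 2
        for out_i, i in enumerate(eeg_idx):
            signals[out_i][rec_idx * spr[i] : (rec_idx + 1) * spr[i]] = rec[
                starts[i] : starts[i + 1]
            ]
        for i in range(n_signals):
            if is_ann[i]:
                ann_chunks.append(rec[starts[i] : starts[i + 1]].tobytes())

    sig = np.empty((len(eeg_idx), n_records * spr[eeg_idx[0]]) if eeg_idx else (0, 0))
    for out_i, i in enumerate(eeg_idx):
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        sig[out_i] = (signals[out_i] - dmin[i]) * scale + pmin[i]

    annotations = _parse_annotations(ann_chunks)
    if eeg_idx:
        fs = spr[eeg_idx[0]] / record_dur
    else:
        fs = 1.0
    return Recording(
        eeg_id=eeg_id or path.stem,
        patient_id=patient_id,
        sampling_rate=fs,
        channel_labels=tuple(labels[i] for i in eeg_idx),
        signal=sig,
        annotations=annotations,
    )


_TAL_RE = re.compile(rb"([+-][0-9.]+)(?:\x15([0-9.]+))?\x14(.*?)\x14", re.S)


def _parse_annotations(chunks: list[bytes]) -> list[Annotation]:
    out: list[Annotation] = []
    for chunk in chunks:
        for tal in chunk.split(b"\x00"):
            if not tal:
                continue
            m = _TAL_RE.match(tal)
            if not m:
                continue
            onset = float(m.group(1))
            duration = float(m.group(2)) if m.group(2) else 0.0
            labels = m.group(3)
            for label in labels.split(b"\x14"):
                text = label.decode("utf-8", errors="replace").strip()
                if text:
                    out.append(Annotation(onset_s=onset, duration_s=duration, label=text))
    out.sort(key=lambda a: a.onset_s)
    return out
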