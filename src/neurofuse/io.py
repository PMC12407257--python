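"""Reading and writing signal files: BDF, SNIRF, CSV + JSON sidecar, BIDS export.

BDF is the 24-bit EDF variant (0xFF``BIOSEMI`` magic).  The writer uses a
small, self-describing dialect: 1-second data records, integer sampling
rates, and the true sample count recorded in the reserved header field
(``NSAMP=``) so record padding is trimmed on read.  SNIRF files are HDF5
trees restricted to continuous-wave intensity (dataType 1) and processed
hemoglobin series (dataType 99999 with HbO/HbR labels).  The CSV dialect is
a samples x channels numeric matrix with a JSON sidecar holding at least
``rate``, ``modality`` and ``labels``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EventTable, Recording, SignalBlock
from .errors import FormatError, MetadataError, ParameterError, SchemaError

FORMATS = ("edf", "bdf", "snirf", "csv_sidecar")

_BDF_DIG_MAX = (1 << 23) - 1


def read_signals(path, format: str) -> SignalBlock:
    """Read one modality's signals from ``path`` as a raw-stage block."""
    if format not in FORMATS:
        raise ParameterError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format in ("edf", "bdf"):
        return _read_bdf(path)
    if format == "snirf":
        return _read_snirf(path)
    return _read_csv_sidecar(path)


def write_signals(block: SignalBlock, path, format: str) -> Path:
    """Write ``block`` so that :func:`read_signals` round-trips it."""
    path = Path(path)
    if format == "bdf":
        _write_bdf(block, path)
    elif format == "snirf":
        if not block.modality.startswith("fnirs"):
            raise FormatError("SNIRF stores fNIRS data only")
        _write_snirf(block, path)
    elif format == "csv_sidecar":
        _write_csv_sidecar(block, path)
    else:
        raise ParameterError(f"unsupported output format {format!r}")
    return path


# ---------------------------------------------------------------------------
# BDF (24-bit EDF variant)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _write_bdf(block: SignalBlock, path: Path) -> None:
    rate = block.rate
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("BDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n = block.n_samples
    n_rec = max(1, -(-n // spr))
    nch = block.n_channels

    pmaxs, pmins = [], []
    for ch in block.data:
        amp = float(np.max(np.abs(ch))) * 1.0001  # headroom for rounding
        amp = amp if amp > 0 else 1.0
        # quantize against the value as it will be re-read from the header
        amp = float(f"{amp:.6g}"[:8])
        pmaxs.append(amp)
        pmins.append(-amp)

    hdr = bytearray()
    hdr += b"\xffBIOSEMI"
    hdr += _pad("", 80)  # patient id
    hdr += _pad(f"modality={block.modality}", 80)
    hdr += _pad("01.01.00", 8)
    hdr += _pad("00.00.00", 8)
    hdr += _pad(str(256 * (1 + nch)), 8)
    hdr += _pad(f"24BIT NSAMP={n}", 44)
    hdr += _pad(str(n_rec), 8)
    hdr += _pad("1", 8)
    hdr += _pad(str(nch), 4)
    for lab in block.labels:
        hdr += _pad(lab, 16)
    hdr += _pad("", 80) * nch  # transducer
    hdr += _pad("uV", 8) * nch
    for p in pmins:
        hdr += _pad(f"{p:.6g}"[:8], 8)
    for p in pmaxs:
        hdr += _pad(f"{p:.6g}"[:8], 8)
    hdr += _pad(str(-_BDF_DIG_MAX - 1), 8) * nch
    hdr += _pad(str(_BDF_DIG_MAX), 8) * nch
    hdr += _pad("", 80) * nch  # prefiltering
    hdr += _pad(str(spr), 8) * nch
    hdr += _pad("", 32) * nch

    padded = np.zeros((nch, n_rec * spr))
    padded[:, :n] = block.data
    pmin = np.array(pmins)[:, None]
    pmax = np.array(pmaxs)[:, None]
    dmin, dmax = -_BDF_DIG_MAX - 1, _BDF_DIG_MAX
    digital = np.rint((padded - pmin) / (pmax - pmin) * (dmax - dmin) + dmin)
    digital = np.clip(digital, dmin, dmax).astype(np.int32)

    with open(path, "wb") as f:
        f.write(bytes(hdr))
        for rec in range(n_rec):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            for ch in range(nch):
                f.write(_int24_pack(chunk[ch]))


def _int24_pack(values: np.ndarray) -> bytes:
    v = values.astype(np.int32)
    out = np.empty((v.size, 3), dtype=np.uint8)
    out[:, 0] = v & 0xFF
    out[:, 1] = (v >> 8) & 0xFF
    out[:, 2] = (v >> 16) & 0xFF
    return out.tobytes()


def _int24_unpack(raw: bytes) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    v = b[:, 0] | (b[:, 1] << 8) | (b[:, 2] << 16)
    v[v >= (1 << 23)] -= 1 << 24
    return v


def _read_bdf(path: Path) -> SignalBlock:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256 or head[:8] != b"\xffBIOSEMI":
            raise FormatError(f"{path} is not a BDF file (bad magic)")
        try:
            recording_id = head[88:168].decode("ascii").strip()
            reserved = head[192:236].decode("ascii")
            n_rec = int(head[236:244])
            rec_dur = float(head[244:252])
            nch = int(head[252:256])
        except ValueError as exc:
            raise FormatError(f"unreadable BDF header in {path}") from exc
        ch_hdr = f.read(256 * nch)
        if len(ch_hdr) < 256 * nch:
            raise FormatError("truncated BDF channel header")

        def fields(offset, width):
            base = offset * nch
            return [ch_hdr[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(nch)]

        labels = fields(0, 16)
        pmin = np.array([float(x) for x in fields(16 + 80 + 8, 8)])
        pmax = np.array([float(x) for x in fields(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(x) for x in fields(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(x) for x in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(x) for x in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise FormatError("per-channel sampling rates are not supported")
        spr = spr[0]
        rate = spr / rec_dur

        data = np.empty((nch, n_rec * spr))
        for rec in range(n_rec):
            for ch in range(nch):
                raw = f.read(3 * spr)
                if len(raw) < 3 * spr:
                    raise FormatError("truncated BDF data section")
                data[ch, rec * spr:(rec + 1) * spr] = _int24_unpack(raw)

    data = (data - dmin[:, None]) / (dmax - dmin)[:, None] \
        * (pmax - pmin)[:, None] + pmin[:, None]
    for token in reserved.split():
        if token.startswith("NSAMP="):
            data = data[:, :int(token[6:])]
    modality = "eeg"
    for token in recording_id.split():
        if token.startswith("modality="):
            modality = token.split("=", 1)[1]
    return SignalBlock(modality, data, rate, labels, stage="raw")


# ---------------------------------------------------------------------------
# SNIRF (HDF5)


def _write_snirf(block: SignalBlock, path: Path) -> None:
    is_hb = block.modality == "fnirs_hb"
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=block.data.T)
        data1.create_dataset("time",
                             data=np.array([block.start_time, 1.0 / block.rate]))
        data1.create_dataset("channelLabels",
                             data=np.array(block.labels, dtype=object),
                             dtype=h5py.string_dtype())
        for i in range(block.n_channels):
            ml = data1.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=i // 2 + 1)
            ml.create_dataset("detectorIndex", data=i // 2 + 1)
            if is_hb:
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("dataTypeLabel", data=block.chromophore[i])
                ml.create_dataset("wavelengthIndex", data=1)
            else:
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("wavelengthIndex", data=i % 2 + 1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))


def _read_snirf(path: Path) -> SignalBlock:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"{path} is not an HDF5/SNIRF file") from exc
    with f:
        if "nirs" in f:
            nirs = f["nirs"]
        elif "nirs1" in f:
            nirs = f["nirs1"]
        else:
            raise FormatError("no /nirs group in SNIRF file")
        data1 = nirs["data1"]
        series = np.asarray(data1["dataTimeSeries"]).T
        time = np.asarray(data1["time"]).ravel()
        if time.size == 2:
            start, dt = float(time[0]), float(time[1])
        else:
            start, dt = float(time[0]), float(np.median(np.diff(time)))
        n_ch = series.shape[0]
        dtypes, chromo = [], []
        for i in range(n_ch):
            ml = data1[f"measurementList{i + 1}"]
            dt_code = int(np.asarray(ml["dataType"]))
            dtypes.append(dt_code)
            if dt_code == 99999:
                label = np.asarray(ml["dataTypeLabel"]).item()
                if isinstance(label, bytes):
                    label = label.decode()
                if label not in ("HbO", "HbR"):
                    raise FormatError(
                        f"unsupported processed dataTypeLabel {label!r}")
                chromo.append(label)
            elif dt_code == 1:
                chromo.append("none")
            else:
                raise FormatError(
                    f"unsupported SNIRF dataType {dt_code} (only CW intensity "
                    "and processed Hb series are handled)")
        if len(set(dtypes)) != 1:
            raise FormatError("mixed SNIRF dataTypes in one data block")
        if "channelLabels" in data1:
            labels = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in np.asarray(data1["channelLabels"])]
        else:
            labels = [f"S{i // 2 + 1}-D{i // 2 + 1}" for i in range(n_ch)]
        modality = "fnirs_hb" if dtypes[0] == 99999 else "fnirs_intensity"
        chromo = chromo if modality == "fnirs_hb" else None
    return SignalBlock(modality, series, 1.0 / dt, labels, chromophore=chromo,
                       start_time=start, stage="raw")


# ---------------------------------------------------------------------------
# CSV + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_csv_sidecar(block: SignalBlock, path: Path) -> None:
    np.savetxt(path, block.data.T, delimiter=",", fmt="%.17g")
    sidecar = {
        "rate": block.rate,
        "modality": block.modality,
        "labels": block.labels,
        "chromophore": block.chromophore,
        "start_time": block.start_time,
        "stage": block.stage,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _read_csv_sidecar(path: Path) -> SignalBlock:
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar {sc_path}")
    try:
        sidecar = json.loads(sc_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"sidecar {sc_path} is not valid JSON") from exc
    for key in ("rate", "modality", "labels"):
        if key not in sidecar:
            raise SchemaError(f"sidecar missing required key {key!r}")
    data = np.loadtxt(path, delimiter=",", ndmin=2).T
    if data.shape[0] != len(sidecar["labels"]):
        raise SchemaError(
            f"sidecar declares {len(sidecar['labels'])} labels but CSV has "
            f"{data.shape[0]} columns")
    return SignalBlock(sidecar["modality"], data, float(sidecar["rate"]),
                       sidecar["labels"],
                       chromophore=sidecar.get("chromophore"),
                       start_time=float(sidecar.get("start_time", 0.0)),
                       stage=sidecar.get("stage", "raw"))


# ---------------------------------------------------------------------------
# BIDS-style export


def export_bids_layout(recording: Recording, root) -> Path:
    """Write a minimal BIDS-like tree ``sub-<id>/[eeg|nirs|...]/...``.

    Each modality gets a data file, a JSON sidecar (sampling rate, channel
    count, task name) and a channels TSV; events, when present, are written
    as a BIDS events TSV per modality directory.
    """
    subject = recording.meta.get("subject")
    task = recording.meta.get("task")
    if not subject or not task:
        raise MetadataError("recording.meta needs non-empty 'subject' and 'task'")
    root = Path(root)
    sub = f"sub-{subject}"
    for key, block in recording.blocks.items():
        if block.modality.startswith("fnirs"):
            moddir, suffix, fmt = "nirs", "nirs", "snirf"
        elif block.modality in ("eeg", "eog"):
            moddir, suffix, fmt = "eeg", "eeg", "bdf"
        else:
            moddir, suffix, fmt = block.modality, block.modality, "csv_sidecar"
        outdir = root / sub / moddir
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{sub}_task-{task}_{suffix}"
        ext = {"bdf": ".bdf", "snirf": ".snirf", "csv_sidecar": ".csv"}[fmt]
        write_signals(block, outdir / (stem + ext), fmt)
        meta = {"SamplingFrequency": block.rate,
                "ChannelCount": block.n_channels,
                "TaskName": task}
        meta_path = outdir / (stem + ".json")
        if fmt == "csv_sidecar":  # merge into the data sidecar, same filename
            meta = {**json.loads(meta_path.read_text()), **meta}
        meta_path.write_text(json.dumps(meta, indent=1))
        channels = pd.DataFrame({"name": block.labels,
                                 "type": [block.modality] * block.n_channels})
        channels.to_csv(outdir / f"{sub}_task-{task}_channels.tsv",
                        sep="\t", index=False)
        events = recording.events_for(key)
        if len(events):
            events.write_tsv(outdir / f"{sub}_task-{task}_events.tsv")
    return root / sub
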