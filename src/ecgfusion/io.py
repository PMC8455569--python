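"""ECG records and peak annotations: containers and readers/writers.

Conventions used throughout the package: 0-based sample indices, half-open
intervals ``[start, stop)``, amplitudes in millivolts.  Native on-disk
formats are plain text: a two-column CSV ``sample_index,mV`` for signals and
a sidecar CSV ``index,label`` (label in {P, R, T}) for annotations.

A minimal WFDB codec (format-16 signal files and the MIT binary annotation
format) is included for interoperability with PhysioNet records such as
MIT-BIH; it covers single- and multi-channel format-16 records, which is
what the MIT-BIH arrhythmia database uses.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ecgfusion")

__all__ = [
    "ECGRecord",
    "PeakAnnotations",
    "read_csv_record",
    "write_csv_record",
    "read_annotations",
    "write_annotations",
    "read_wfdb",
    "write_wfdb",
    "read_wfdb_annotations",
    "BEAT_CLASS_MAP",
]

#: MIT-BIH beat-type annotation codes -> class labels (single-character
#: symbols as used in the .atr files of the arrhythmia database)
BEAT_CLASS_MAP = {
    "N": "Normal",
    "L": "LBBB",
    "R": "RBBB",
    "/": "PACE",
    "V": "PVC",
    "A": "APC",
}


@dataclass
class ECGRecord:
    """A sampled single-lead ECG.

    Attributes
    ----------
    samples : numpy.ndarray
        Signal in mV.
    fs : float
        Sampling rate in Hz.
    record_id : str
        Identifier of the source record.
    lead : str
        Lead name (MIT-BIH modified limb lead II by default).
    age, sex, rhythm_label : optional patient metadata used by the
        classification stage (sex is "M" or "F").
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""
    lead: str = "MLII"
    age: float | None = None
    sex: str | None = None
    rhythm_label: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("ECGRecord needs a non-empty 1-D sample array")
        if not np.isfinite(self.samples).all():
            raise ValueError("ECGRecord samples contain NaN/inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Copy of this record with a new sample array (metadata kept)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class PeakAnnotations:
    """P/R/T peak sample indices for one record (each strictly increasing)."""

    p_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    r_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    t_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        for name in ("p_indices", "r_indices", "t_indices"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if idx.size and not np.all(np.diff(idx) > 0):
                warnings.warn(f"{name} not strictly increasing; sorting")
                idx = np.unique(idx)
            setattr(self, name, idx)

    def check_bounds(self, n: int) -> None:
        for name in ("p_indices", "r_indices", "t_indices"):
            idx = getattr(self, name)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"{name} outside record of length {n}")


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def read_csv_record(path, fs: float, record_id: str | None = None, **meta) -> ECGRecord:
    """Read a one- or two-column numeric CSV as an ECG record.

    A non-numeric header row is skipped automatically.  With two columns the
    second is taken as the amplitude (mV); with one column, the first.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, comment="#")
    # drop a header row if the last column does not parse as a number
    try:
        float(df.iloc[0, df.shape[1] - 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"{path}: no samples")
    col = df.iloc[:, 1] if df.shape[1] >= 2 else df.iloc[:, 0]
    samples = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
    return ECGRecord(samples, fs, record_id=record_id or path.stem, **meta)


def write_csv_record(record: ECGRecord, path) -> None:
    """Write ``sample_index,mV`` with a header row."""
    df = pd.DataFrame(
        {"sample_index": np.arange(len(record)), "mV": record.samples}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations(path) -> PeakAnnotations:
    """Read a sidecar annotation CSV (``index,label``; label in {P, R, T}).

    Unknown labels are skipped with a warning; out-of-order indices are
    sorted.  An empty file yields empty annotations.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        return PeakAnnotations()
    df = pd.read_csv(path, header=None, comment="#")
    try:
        int(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        return PeakAnnotations()
    groups: dict[str, list[int]] = {"P": [], "R": [], "T": []}
    skipped = 0
    for _, row in df.iterrows():
        label = str(row.iloc[1]).strip().upper()
        if label in groups:
            groups[label].append(int(row.iloc[0]))
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} annotation(s) with unknown label")
    return PeakAnnotations(
        p_indices=sorted(groups["P"]),
        r_indices=sorted(groups["R"]),
        t_indices=sorted(groups["T"]),
    )


def write_annotations(ann: PeakAnnotations, path) -> None:
    rows = [(int(i), lab) for lab, idx in
            (("P", ann.p_indices), ("R", ann.r_indices), ("T", ann.t_indices))
            for i in idx]
    rows.sort()
    pd.DataFrame(rows, columns=["index", "label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Minimal WFDB codec (header + format-16 .dat, MIT annotation format)
# ---------------------------------------------------------------------------

def read_wfdb(path, channel: str = "MLII") -> ECGRecord:
    """Read one channel of a WFDB record (format-16 signal files).

    ``path`` is the record path without extension (``.../100`` reads
    ``100.hea`` and the signal file it names).  Samples are converted to
    physical units (mV) via the header's gain and baseline.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing header file {hea}")
    lines = [ln.split("#")[0].strip() for ln in hea.read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    rec_name, nsig, fs, nsamp = _parse_wfdb_record_line(lines[0])
    sigs = [_parse_wfdb_signal_line(ln) for ln in lines[1: 1 + nsig]]
    leads = [s["description"] for s in sigs]
    if channel not in leads:
        raise ValueError(f"lead {channel!r} not in record {rec_name}; available: {leads}")
    ch = leads.index(channel)
    if any(s["format"] != 16 for s in sigs):
        raise NotImplementedError("only WFDB signal format 16 is supported")
    dat = path.parent / sigs[ch]["file_name"]
    raw = np.fromfile(dat, dtype="<i2")
    raw = raw[: nsamp * nsig].reshape(-1, nsig)
    adc = raw[:, ch].astype(float)
    mv = (adc - sigs[ch]["baseline"]) / sigs[ch]["gain"]
    return ECGRecord(mv, float(fs), record_id=rec_name, lead=channel)


def write_wfdb(record: ECGRecord, path, gain: float = 200.0) -> None:
    """Write a single-channel format-16 WFDB record (header + .dat)."""
    path = Path(path)
    adc = np.round(record.samples * gain).astype("<i2")
    dat_name = path.name + ".dat"
    checksum = int(np.sum(adc.astype(np.int64)) % 65536)
    hdr = (
        f"{path.name} 1 {record.fs:g} {len(record)}\n"
        f"{dat_name} 16 {gain:g}(0)/mV 16 0 {int(adc[0])} {checksum} 0 {record.lead}\n"
    )
    path.with_suffix(".hea").write_text(hdr)
    adc.tofile(path.parent / dat_name)


def _parse_wfdb_record_line(line: str):
    parts = line.split()
    name = parts[0].split("/")[0]
    nsig = int(parts[1])
    fs = float(parts[2].split("/")[0]) if len(parts) > 2 else 250.0
    nsamp = int(parts[3]) if len(parts) > 3 else 0
    return name, nsig, fs, nsamp


def _parse_wfdb_signal_line(line: str):
    parts = line.split()
    fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
    gain_spec = parts[2] if len(parts) > 2 else "200"
    gain_str = gain_spec.split("/")[0]
    if "(" in gain_str:
        gain, baseline = gain_str[:-1].split("(")
    else:
        gain, baseline = gain_str, "0"
    g = float(gain) if float(gain) != 0 else 200.0
    return {
        "file_name": parts[0],
        "format": fmt,
        "gain": g,
        "baseline": int(baseline),
        "description": " ".join(parts[8:]) if len(parts) > 8 else "",
    }


#: MIT annotation type codes for beats whose R location we keep, and for
#: the p/t wave symbols written by wave-delineation annotators
_MIT_BEAT_CODES = set(range(1, 14)) | {25, 34, 35, 38}
_MIT_PWAVE_CODE = 24  # 'p'
_MIT_TWAVE_CODE = 27  # 't'


def read_wfdb_annotations(path) -> PeakAnnotations:
    """Read a binary MIT-format annotation file (e.g. ``100.atr``).

    Beat annotations map to ``r_indices``; 'p' and 't' wave annotations, when
    present, map to ``p_indices`` / ``t_indices``.
    """
    data = Path(path).read_bytes()
    time = 0
    i = 0
    r, p, t = [], [], []
    while i + 1 < len(data):
        lo, hi = data[i], data[i + 1]
        code = hi >> 2
        interval = ((hi & 0x03) << 8) | lo
        i += 2
        if code == 0 and interval == 0:  # EOF
            break
        if code == 59:  # SKIP: next 4 bytes are a long interval
            if i + 3 < len(data):
                time += struct.unpack("<i", bytes(
                    [data[i + 2], data[i + 3], data[i], data[i + 1]]))[0]
                i += 4
            continue
        if code == 63:  # AUX: interval bytes of payload, padded to even
            i += interval + (interval & 1)
            continue
        if code in (60, 61, 62):  # NUM/SUB/CHN modifiers
            continue
        time += interval
        if code in _MIT_BEAT_CODES:
            r.append(time)
        elif code == _MIT_PWAVE_CODE:
            p.append(time)
        elif code == _MIT_TWAVE_CODE:
            t.append(time)
    return PeakAnnotations(p_indices=p, r_indices=r, t_indices=t)
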