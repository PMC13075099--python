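"""Record readers and writers.

Native round-trip format: signal as one-sample-per-row CSV written at
17 significant digits (bit-exact for float64), annotations as CSV with
a ``sample_index`` column, metadata as JSON. Also provided: a minimal
reader for WFDB records (text ``.hea`` header plus format 16 or 212
``.dat`` payloads) and the DaISy whitespace ASCII matrix (time column
followed by eight signal channels at 250 Hz).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .records import AnnotatedAECG

__all__ = [
    "write_record",
    "read_record",
    "read_wfdb_record",
    "read_daisy_ascii",
]


def write_record(rec: AnnotatedAECG, basepath: str | Path) -> None:
    """Write a record as ``<base>.csv`` + ``<base>.meta.json`` (+
    ``<base>.<kind>_rpeaks.csv`` per annotation array present)."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    cols = {"signal": rec.signal}
    if rec.fetal_clean is not None:
        cols["fetal_clean"] = rec.fetal_clean
    if rec.maternal_clean is not None:
        cols["maternal_clean"] = rec.maternal_clean
    header = ",".join(cols)
    data = np.column_stack(list(cols.values()))
    np.savetxt(base.with_suffix(".csv"), data, delimiter=",", header=header, comments="", fmt="%.17g")
    for kind in ("fetal", "maternal"):
        idx = getattr(rec, f"{kind}_rpeaks")
        if idx.size:
            np.savetxt(
                base.parent / f"{base.name}.{kind}_rpeaks.csv",
                idx[:, None],
                header="sample_index",
                comments="",
                fmt="%d",
            )
    meta = {"fs": rec.fs, "subject_id": rec.subject_id, "n_samples": int(rec.signal.size)}
    (base.parent / f"{base.name}.meta.json").write_text(json.dumps(meta, indent=1))


def read_record(basepath: str | Path) -> AnnotatedAECG:
    """Read a record written by :func:`write_record` (bit-exact)."""
    base = Path(basepath)
    meta = json.loads((base.parent / f"{base.name}.meta.json").read_text())
    raw = np.genfromtxt(base.with_suffix(".csv"), delimiter=",", names=True)
    names = raw.dtype.names

    def col(name):
        return raw[name].astype(np.float64) if name in names else None

    def peaks(kind):
        p = base.parent / f"{base.name}.{kind}_rpeaks.csv"
        if not p.exists():
            return np.empty(0, np.int64)
        return np.atleast_1d(np.loadtxt(p, skiprows=1, dtype=np.int64))

    return AnnotatedAECG(
        signal=col("signal"),
        fs=float(meta["fs"]),
        fetal_rpeaks=peaks("fetal"),
        maternal_rpeaks=peaks("maternal"),
        fetal_clean=col("fetal_clean"),
        maternal_clean=col("maternal_clean"),
        subject_id=meta.get("subject_id", base.name),
    )


def _read_dat(path: Path, n_sig: int, fmt: str) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == "16":
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        n = flat.size // n_sig
        return flat[: n * n_sig].reshape(n, n_sig)
    if fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
        b = b[: (b.size // 3) * 3].reshape(-1, 3)
        s1 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        s2 = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        s2 = np.where(s2 > 2047, s2 - 4096, s2)
        flat = np.column_stack([s1, s2]).reshape(-1)
        n = flat.size // n_sig
        return flat[: n * n_sig].reshape(n, n_sig)
    raise ValueError(f"unsupported WFDB signal format: {fmt}")


def read_wfdb_record(path: str | Path, channel: int = 0) -> AnnotatedAECG:
    """Read one channel of a WFDB record (formats 16 and 212).

    ``path`` is the record path without extension. Gain/baseline from
    the header are applied to yield physical units. Fetal R-peak
    annotations are loaded from a ``<record>.fetal_rpeaks.csv`` sidecar
    when present (binary ``.atr`` annotations are not parsed).
    """
    base = Path(path)
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header at {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if not 0 <= channel < n_sig:
        names = [ln.split()[-1] for ln in lines[1 : 1 + n_sig]]
        raise ValueError(f"channel {channel} not in record; available: {names}")
    sig_line = lines[1 + channel].split()
    fname = sig_line[0]
    fmt = sig_line[1].split("x")[0].split(":")[0].split("+")[0]
    gain = 200.0
    baseline = 0
    if len(sig_line) > 2:
        gain_field = sig_line[2]
        if "(" in gain_field:
            gain_s, rest = gain_field.split("(", 1)
            gain = float(gain_s)
            baseline = int(rest.split(")", 1)[0])
        else:
            gain = float(gain_field.split("/")[0])
    if gain == 0:
        gain = 200.0
    data = _read_dat(base.parent / fname, n_sig, fmt)
    signal = (data[:, channel] - baseline) / gain
    fpeaks_path = base.parent / f"{base.name}.fetal_rpeaks.csv"
    fpeaks = (
        np.atleast_1d(np.loadtxt(fpeaks_path, skiprows=1, dtype=np.int64))
        if fpeaks_path.exists()
        else np.empty(0, np.int64)
    )
    return AnnotatedAECG(signal=signal, fs=fs, fetal_rpeaks=fpeaks, subject_id=base.name)


def read_daisy_ascii(path: str | Path, channel: int = 1, fs: float = 250.0) -> AnnotatedAECG:
    """Read one channel of a DaISy-style ASCII matrix.

    The file is a whitespace-delimited numeric matrix whose first
    column is time and whose remaining eight columns are signals;
    ``channel`` is 1-based over the signal columns.
    """
    p = Path(path)
    try:
        mat = np.loadtxt(p)
    except ValueError as exc:
        raise ValueError(f"non-numeric content in {p}: {exc}") from exc
    mat = np.atleast_2d(mat)
    n_channels = mat.shape[1] - 1
    if not 1 <= channel <= n_channels:
        raise ValueError(f"channel must be in 1..{n_channels}")
    return AnnotatedAECG(signal=mat[:, channel], fs=fs, subject_id=f"{p.stem}-ch{channel}")
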