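"""Reading and writing ECG records: WFDB and CSV layouts, label mapping.

Two on-disk layouts are supported:

* **WFDB** (MIT-BIH style): a text header ``<id>.hea``, a format-16
  little-endian int16 signal file ``<id>.dat``, and optionally a MIT-format
  annotation file ``<id>.atr`` holding beat symbols at R-peak sample
  indices.  The codec here is a minimal implementation covering format 16
  and the beat-annotation subset (including SKIP/NUM/SUB/CHN/AUX
  pseudo-annotations on read); it is not a full WFDB library.
* **CSV** (SPH style): one file per record with one lead per column and a
  header row, plus a ``labels.csv`` (record_id,label) giving each record's
  rhythm label.  CSV records carry no R-peak annotations; a detector is
  used downstream.

Raw annotation symbols / rhythm codes are mapped onto analysis classes
through a LabelMap.  Defaults ship for the AAMI EC57 five-class beat
grouping (N/S/V/F/Q) and the 11-to-4 rhythm merge (AFIB/GSVT/SB/SR); both
are plain data and can be replaced or loaded from YAML.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LabelMap",
    "DatasetSpec",
    "EcgRecord",
    "AAMI_LABEL_MAP",
    "SPH_LABEL_MAP",
    "MITBIH_EXCLUDED_RECORDS",
    "load_record",
    "iter_dataset",
    "write_wfdb",
    "write_csv_record",
    "read_wfdb",
]

# MIT annotation code <-> symbol for the beat types we handle.
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: Records whose MLII lead is absent or paced in the standard 48-record set.
MITBIH_EXCLUDED_RECORDS = ("102", "104", "114")


@dataclass(frozen=True)
class LabelMap:
    scheme_name: str
    raw_to_class: dict[str, str]
    classes: tuple[str, ...]

    def __post_init__(self):
        if not self.classes:
            raise ValueError("class list must be non-empty")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class list contains duplicates")
        stray = set(self.raw_to_class.values()) - set(self.classes)
        if stray:
            raise ValueError(f"mapped values not in class list: {sorted(stray)}")

    @classmethod
    def from_yaml(cls, path) -> "LabelMap":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            scheme_name=d["scheme_name"],
            raw_to_class=dict(d["raw_to_class"]),
            classes=tuple(d["classes"]),
        )


AAMI_LABEL_MAP = LabelMap(
    scheme_name="aami-ec57",
    raw_to_class={
        "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
        "A": "S", "a": "S", "J": "S", "S": "S",
        "V": "V", "E": "V",
        "F": "F",
        "/": "Q", "f": "Q", "Q": "Q",
    },
    classes=("N", "S", "V", "F", "Q"),
)

SPH_LABEL_MAP = LabelMap(
    scheme_name="sph-4-rhythm",
    raw_to_class={
        "SB": "SB",
        "SR": "SR", "SI": "SR",
        "AFIB": "AFIB", "AF": "AFIB",
        "SVT": "GSVT", "AT": "GSVT", "SAAWR": "GSVT",
        "ST": "GSVT", "AVNRT": "GSVT", "AVRT": "GSVT",
    },
    classes=("AFIB", "GSVT", "SB", "SR"),
)


@dataclass(frozen=True)
class DatasetSpec:
    source_path: str
    layout: str  # "wfdb" | "csv"
    lead_name: str = "MLII"
    excluded_record_ids: tuple[str, ...] = ()
    sampling_rate: float | None = None  # override; None = from file / required for csv
    label_map: LabelMap = AAMI_LABEL_MAP

    def __post_init__(self):
        if self.layout not in ("wfdb", "csv"):
            raise ValueError("layout must be 'wfdb' or 'csv'")
        if self.sampling_rate is not None and self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class EcgRecord:
    """One continuous analysis lead with optional beat or rhythm labels."""

    record_id: str
    samples: np.ndarray
    sampling_rate: float
    r_peaks: np.ndarray | None = None
    beat_labels: list[str] | None = None
    rhythm_label: str | None = None
    n_dropped_annotations: int = 0


# ---------------------------------------------------------------------------
# WFDB codec (minimal: format 16, beat annotations)
# ---------------------------------------------------------------------------


def write_wfdb(
    directory,
    record_id: str,
    signals: dict[str, np.ndarray],
    sampling_rate: float,
    r_peaks: np.ndarray | None = None,
    symbols: list[str] | None = None,
    gain: float = 200.0,
) -> None:
    """Write a format-16 record (and annotations, if peaks are given)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = list(signals)
    arrays = [np.asarray(signals[n], dtype=float) for n in names]
    n_samp = arrays[0].size
    adc = np.stack([np.clip(np.round(a * gain), -32768, 32767) for a in arrays], axis=1)
    adc = adc.astype("<i2")
    (directory / f"{record_id}.dat").write_bytes(adc.tobytes())

    lines = [f"{record_id} {len(names)} {sampling_rate:g} {n_samp}"]
    for j, name in enumerate(names):
        init = int(adc[0, j]) if n_samp else 0
        lines.append(f"{record_id}.dat 16 {gain:g}(0)/mV 16 0 {init} 0 0 {name}")
    (directory / f"{record_id}.hea").write_text("\n".join(lines) + "\n")

    if r_peaks is not None:
        if symbols is None or len(symbols) != len(r_peaks):
            raise ValueError("one annotation symbol per R-peak required")
        buf = bytearray()
        prev = 0
        for t, sym in zip(r_peaks, symbols):
            code = _SYMBOL_TO_CODE.get(sym)
            if code is None:
                raise ValueError(f"unsupported annotation symbol {sym!r}")
            dt = int(t) - prev
            if dt >= 1024:
                buf += struct.pack("<H", _SKIP << 10)
                buf += struct.pack("<H", (dt >> 16) & 0xFFFF)
                buf += struct.pack("<H", dt & 0xFFFF)
                dt = 0
            buf += struct.pack("<H", (code << 10) | (dt & 0x3FF))
            prev = int(t)
        buf += struct.pack("<H", 0)  # end of annotations
        (directory / f"{record_id}.atr").write_bytes(bytes(buf))


def _read_annotations(path: Path) -> tuple[np.ndarray, list[str]]:
    data = path.read_bytes()
    times, symbols = [], []
    t = 0
    i = 0
    pending_skip = 0
    while i + 2 <= len(data):
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
            i += interval + (interval % 2)
            continue
        t += interval + pending_skip
        pending_skip = 0
        symbols.append(_CODE_TO_SYMBOL.get(code, "?"))
        times.append(t)
    return np.asarray(times, dtype=int), symbols


def read_wfdb(directory, record_id: str):
    """Read header, signals (mV) and annotations of one record.

    Returns (signal dict name->mV array, sampling rate, annotation times,
    annotation symbols); the annotation entries are empty when no ``.atr``
    file exists.
    """
    directory = Path(directory)
    header = (directory / f"{record_id}.hea").read_text().strip().splitlines()
    first = header[0].split()
    n_sig, fs, n_samp = int(first[1]), float(first[2]), int(first[3])
    names, gains, baselines = [], [], []
    for line in header[1 : 1 + n_sig]:
        tok = line.split()
        if tok[1] != "16":
            raise ValueError(f"unsupported WFDB signal format {tok[1]!r} (only 16)")
        gspec = tok[2].split("/")[0]
        if "(" in gspec:
            g, b = gspec.rstrip(")").split("(")
        else:
            g, b = gspec, "0"
        gains.append(float(g) if float(g) != 0 else 200.0)
        baselines.append(float(b))
        names.append(tok[8] if len(tok) > 8 else f"sig{len(names)}")
    raw = np.frombuffer((directory / f"{record_id}.dat").read_bytes(), dtype="<i2")
    raw = raw.reshape(-1, n_sig)[:n_samp]
    sigs = {
        name: (raw[:, j].astype(float) - baselines[j]) / gains[j] for j, name in enumerate(names)
    }
    atr = directory / f"{record_id}.atr"
    if atr.exists():
        times, symbols = _read_annotations(atr)
    else:
        times, symbols = np.array([], dtype=int), []
    return sigs, fs, times, symbols


# ---------------------------------------------------------------------------
# CSV layout
# ---------------------------------------------------------------------------


def write_csv_record(directory, record_id: str, signals: dict[str, np.ndarray]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(signals).to_csv(directory / f"{record_id}.csv", index=False)


def _read_rhythm_labels(directory: Path) -> dict[str, str]:
    path = directory / "labels.csv"
    if not path.exists():
        return {}
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Loading through a DatasetSpec
# ---------------------------------------------------------------------------


def load_record(spec: DatasetSpec, record_id: str) -> EcgRecord:
    """Load one record's analysis lead, with labels mapped to classes.

    Beat annotations whose symbol has no entry in the label map are dropped
    and counted in ``n_dropped_annotations``.
    """
    src = Path(spec.source_path)
    if spec.layout == "wfdb":
        sigs, fs, times, symbols = read_wfdb(src, record_id)
        if spec.lead_name not in sigs:
            raise KeyError(
                f"lead {spec.lead_name!r} not in record {record_id} (has {sorted(sigs)})"
            )
        mapped, kept_times, dropped = [], [], 0
        for t, s in zip(times, symbols):
            cls = spec.label_map.raw_to_class.get(s)
            if cls is None:
                dropped += 1
            else:
                mapped.append(cls)
                kept_times.append(t)
        return EcgRecord(
            record_id=record_id,
            samples=sigs[spec.lead_name],
            sampling_rate=spec.sampling_rate or fs,
            r_peaks=np.asarray(kept_times, dtype=int) if len(symbols) else None,
            beat_labels=mapped if len(symbols) else None,
            n_dropped_annotations=dropped,
        )

    df = pd.read_csv(src / f"{record_id}.csv")
    if spec.lead_name not in df.columns:
        raise KeyError(f"lead {spec.lead_name!r} not in record {record_id} columns")
    if spec.sampling_rate is None:
        raise ValueError("CSV layout requires an explicit sampling_rate")
    raw_label = _read_rhythm_labels(src).get(record_id)
    rhythm = spec.label_map.raw_to_class.get(raw_label) if raw_label is not None else None
    return EcgRecord(
        record_id=record_id,
        samples=df[spec.lead_name].to_numpy(dtype=float),
        sampling_rate=spec.sampling_rate,
        rhythm_label=rhythm,
    )


def list_record_ids(spec: DatasetSpec) -> list[str]:
    src = Path(spec.source_path)
    suffix = ".hea" if spec.layout == "wfdb" else ".csv"
    ids = sorted(
        p.stem for p in src.glob(f"*{suffix}") if p.name != "labels.csv"
    )
    return [r for r in ids if r not in set(spec.excluded_record_ids)]


def iter_dataset(spec: DatasetSpec):
    """Yield records sorted by id, skipping excluded ids; warns when empty."""
    ids = list_record_ids(spec)
    if not ids:
        warnings.warn(f"no records found under {spec.source_path}")
    for rid in ids:
        yield load_record(spec, rid)
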