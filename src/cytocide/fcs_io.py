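"""Event-table container and FCS/CSV input-output.

Flow-cytometry event data are held as a dense ``n_events x n_channels``
matrix of non-negative pulse intensities with an ordered channel list and
acquisition metadata (flow rate, sampled volume, acquisition duration).
Files are read and written in two dialects:

* ``fcs`` -- FCS 3.1 list-mode, single data segment, 32-bit float.  FCS 3.0
  files and integer/double data are accepted on read (integer data are
  widened to float).
* ``csv`` -- a plain comma-separated table whose header row holds the
  channel names, with an optional JSON metadata sidecar
  (``<name>.meta.json``) carrying ``flow_rate_ul_per_min``, ``volume_ul``,
  ``duration_s`` and ``sample_id``.

The ``$VOL`` keyword is interpreted as nanolitres (the common instrument
convention); callers may override the volume explicitly.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "EventTable",
    "FcsFormatError",
    "CANONICAL_CHANNELS",
    "read_events",
    "write_events",
]

#: Canonical channel names for a blue-laser small-particle setup: forward and
#: side scatter plus the green (SYTO9) and red (PI) fluorescence detectors,
#: each as pulse height (-H) and pulse area (-A).  Subsets are allowed.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "FSC-H", "FSC-A", "SSC-H", "SSC-A", "FL1-H", "FL1-A", "FL3-H", "FL3-A",
)

# Accepted spellings for each canonical channel (case-insensitive; '_' and
# '.' treated as '-').  FL2/FL4 are deliberately not mapped.
_ALIASES: dict[str, str] = {}
for _name in CANONICAL_CHANNELS:
    _stem, _suffix = _name.split("-")
    _long = {"H": "Height", "A": "Area"}[_suffix]
    for _alias in (_name, f"{_stem}-{_long}", f"{_stem} {_suffix}"):
        _ALIASES[_alias.upper().replace("_", "-").replace(".", "-")] = _name


class FcsFormatError(ValueError):
    """A file violates the FCS layout or lacks a required keyword."""


def canonical_channel(name: str) -> str:
    """Map an accepted channel spelling onto its canonical name.

    Raises ``ValueError`` listing the accepted aliases when the name is not
    recognised.
    """
    key = name.strip().upper().replace("_", "-").replace(".", "-")
    try:
        return _ALIASES[key]
    except KeyError:
        accepted = ", ".join(sorted(set(_ALIASES)))
        raise ValueError(
            f"unknown channel name {name!r}; accepted names/aliases: {accepted}"
        ) from None


@dataclass(frozen=True)
class AcquisitionMeta:
    """Volumetric acquisition settings.

    The default flow rate (35 uL/min) and sampled volume (25 uL) are the
    instrument settings of the assay this package implements; when the
    duration is not recorded it is derived as ``60 * volume / flow_rate``.
    """

    flow_rate_ul_per_min: float = 35.0
    volume_ul: float = 25.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.flow_rate_ul_per_min <= 0:
            raise ValueError("flow_rate_ul_per_min must be > 0")
        if self.volume_ul <= 0:
            raise ValueError("volume_ul must be > 0")
        if self.duration_s is None:
            object.__setattr__(
                self, "duration_s",
                60.0 * self.volume_ul / self.flow_rate_ul_per_min,
            )
        elif self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        else:
            derived = 60.0 * self.volume_ul / self.flow_rate_ul_per_min
            if abs(self.duration_s - derived) > 0.01 * derived:
                raise ValueError(
                    f"duration_s={self.duration_s} inconsistent with "
                    f"volume/flow rate (expected ~{derived:.3f} s)"
                )


@dataclass
class EventTable:
    """Per-event channel intensities plus acquisition metadata."""

    events: np.ndarray
    channel_names: list[str]
    acquisition: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim == 1:
            self.events = self.events.reshape(0, len(self.channel_names))
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D matrix")
        self.channel_names = [canonical_channel(c) for c in self.channel_names]
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.events.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.events.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if self.events.size and not np.all(np.isfinite(self.events)):
            raise ValueError("intensities must be finite")
        if self.events.size and self.events.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Column vector for one channel."""
        name = canonical_channel(name)
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in table (has {self.channel_names})"
            ) from None
        return self.events[:, idx]

    def has_channel(self, name: str) -> bool:
        return canonical_channel(name) in self.channel_names

    def select(self, mask: np.ndarray) -> "EventTable":
        """New table keeping the events where ``mask`` is true."""
        return EventTable(
            self.events[np.asarray(mask, dtype=bool)],
            list(self.channel_names),
            self.acquisition,
            self.sample_id,
        )

    def with_events(self, events: np.ndarray) -> "EventTable":
        return EventTable(events, list(self.channel_names),
                          self.acquisition, self.sample_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=self.channel_names)


# ---------------------------------------------------------------------------
# FCS dialect


def _compose_text(keywords: dict[str, str], delim: str = "/") -> bytes:
    parts = [delim]
    for key, value in keywords.items():
        parts.append(f"{key}{delim}{value}{delim}")
    return "".join(parts).encode("ascii")


def _write_fcs(table: EventTable, path: Path) -> None:
    data = np.ascontiguousarray(table.events, dtype="<f4")
    data_bytes = data.tobytes()
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(table.n_channels),
        "$TOT": str(table.n_events),
    }
    for i, name in enumerate(table.channel_names, start=1):
        rng = table.events[:, i - 1].max() if table.n_events else 0.0
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)
    acq = table.acquisition
    keywords["$VOL"] = f"{acq.volume_ul * 1000.0:.6g}"  # nanolitres
    keywords["FLOWRATE"] = f"{acq.flow_rate_ul_per_min:.6g}"
    keywords["DURATION"] = f"{acq.duration_s:.6g}"
    if table.sample_id:
        keywords["$FIL"] = table.sample_id

    # Offsets appear inside the text segment, so iterate until stable.
    header_len = 58
    begin_data = end_data = 0
    for _ in range(4):
        keywords["$BEGINDATA"] = str(begin_data)
        keywords["$ENDDATA"] = str(end_data)
        text = _compose_text(keywords)
        new_begin = header_len + len(text)
        new_end = new_begin + max(len(data_bytes) - 1, 0)
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    keywords["$BEGINDATA"] = str(begin_data)
    keywords["$ENDDATA"] = str(end_data)
    text = _compose_text(keywords)

    begin_text = header_len
    end_text = begin_text + len(text) - 1
    header = b"FCS3.1    "
    for value in (begin_text, end_text,
                  begin_data if end_data <= 99_999_999 else 0,
                  end_data if end_data <= 99_999_999 else 0,
                  0, 0):
        header += f"{value:>8d}".encode("ascii")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    body = raw.decode("latin-1")
    parts = body.split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        parts = parts[:-1]
    return {parts[i].strip().upper(): parts[i + 1]
            for i in range(0, len(parts), 2)}


def _read_fcs(path: Path) -> EventTable:
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FcsFormatError("file too short for an FCS header")
    version = blob[:6].decode("latin-1")
    if not version.startswith("FCS3"):
        raise FcsFormatError(f"unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        text = blob[lo:hi].decode("latin-1").strip() or "0"
        return int(text)

    begin_text, end_text = _offset(10, 18), _offset(18, 26)
    begin_data, end_data = _offset(26, 34), _offset(34, 42)
    keywords = _parse_text_segment(blob[begin_text:end_text + 1])

    for required in ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD", "$MODE"):
        if required not in keywords:
            raise FcsFormatError(f"missing required keyword {required}")
    if keywords["$MODE"].strip().upper() != "L":
        raise FcsFormatError("only list-mode ($MODE=L) files are supported")
    n_events = int(keywords["$TOT"])
    n_par = int(keywords["$PAR"])
    names = []
    for i in range(1, n_par + 1):
        key = f"$P{i}N"
        if key not in keywords:
            raise FcsFormatError(f"missing required keyword {key}")
        names.append(keywords[key].strip())

    if begin_data == 0 and "$BEGINDATA" in keywords:
        begin_data = int(keywords["$BEGINDATA"])
        end_data = int(keywords["$ENDDATA"])
    byteord = keywords["$BYTEORD"].strip()
    endian = "<" if byteord.startswith("1") else ">"
    datatype = keywords["$DATATYPE"].strip().upper()
    if datatype == "F":
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        widths = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(widths) != 1:
            raise FcsFormatError("mixed integer widths are not supported")
        dtype = np.dtype(f"{endian}u{widths.pop() // 8}")
    else:
        raise FcsFormatError(f"unsupported $DATATYPE {datatype!r}")

    n_values = n_events * n_par
    raw = blob[begin_data:begin_data + n_values * dtype.itemsize]
    if len(raw) < n_values * dtype.itemsize:
        raise FcsFormatError("data segment shorter than $TOT x $PAR values")
    events = np.frombuffer(raw, dtype=dtype).astype(float).reshape(n_events, n_par)

    vol_nl = float(keywords["$VOL"]) if "$VOL" in keywords else None
    flow = float(keywords["FLOWRATE"]) if "FLOWRATE" in keywords else 35.0
    volume_ul = vol_nl / 1000.0 if vol_nl else 25.0
    acq = AcquisitionMeta(flow_rate_ul_per_min=flow, volume_ul=volume_ul)
    sample_id = keywords.get("$FIL", "").strip()
    return EventTable(events, names, acq, sample_id)


# ---------------------------------------------------------------------------
# CSV dialect


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _write_csv(table: EventTable, path: Path) -> None:
    table.to_dataframe().to_csv(path, index=False)
    meta = {
        "flow_rate_ul_per_min": table.acquisition.flow_rate_ul_per_min,
        "volume_ul": table.acquisition.volume_ul,
        "duration_s": table.acquisition.duration_s,
        "sample_id": table.sample_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_csv(path: Path) -> EventTable:
    frame = pd.read_csv(path)
    if frame.columns.size == 0:
        raise FcsFormatError("CSV has no header row of channel names")
    sidecar = _sidecar_path(path)
    acq = AcquisitionMeta()
    sample_id = ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sample_id = meta.pop("sample_id", "") or ""
        acq = AcquisitionMeta(**{k: v for k, v in meta.items() if v is not None})
    values = frame.to_numpy(dtype=float) if len(frame) else np.empty((0, frame.columns.size))
    return EventTable(values, list(frame.columns), acq, sample_id)


# ---------------------------------------------------------------------------
# Public entry points


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("fcs", "csv"):
            raise ValueError("dialect must be 'fcs' or 'csv'")
        return dialect
    return "fcs" if path.suffix.lower() == ".fcs" else "csv"


def read_events(path: str | Path, dialect: str | None = None) -> EventTable:
    """Read an event table from an FCS 3.0/3.1 or CSV file.

    The dialect is inferred from the extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_dialect(path, dialect) == "fcs":
        return _read_fcs(path)
    return _read_csv(path)


def write_events(table: EventTable, path: str | Path,
                 dialect: str | None = None) -> Path:
    """Write an event table; returns the path written."""
    path = Path(path)
    if _infer_dialect(path, dialect) == "fcs":
        _write_fcs(table, path)
    else:
        _write_csv(table, path)
    return path
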