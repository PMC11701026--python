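"""Thermogram file round-tripping and parameter-log helpers.

Thermogram files are delimited text with a ``time_h,power_nW`` header;
``#``-prefixed comment lines carry metadata (label, volume_mL, corrected,
cut_time_h).  The reader tolerates CRLF line endings and comma or tab
delimiters; the writer emits canonical comma-separated values with 9
significant digits.  When any point is mask-excluded, a third ``included``
column (0/1) preserves the mask so corrections stay reversible on disk.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .thermogram import Thermogram

__all__ = ["read_thermogram", "write_thermogram", "write_param_log"]

_TRUE = {"true", "1", "yes"}


class ThermogramParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}, line {line_no}: {message}")
        self.line_no = line_no


def read_thermogram(path) -> Thermogram:
    """Read a thermogram text file (power stored in nW, returned in W)."""
    path = Path(path)
    text = path.read_text()
    meta: dict[str, str] = {}
    t, p, inc = [], [], []
    header_seen = False
    ncols = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        fields = line.replace("\t", ",").split(",")
        fields = [f.strip() for f in fields if f.strip() != ""]
        if not header_seen:
            if fields[0].lower() != "time_h":
                raise ThermogramParseError(path, line_no,
                                           f"expected 'time_h' header, got {fields!r}")
            ncols = len(fields)
            header_seen = True
            continue
        if ncols is not None and len(fields) != ncols:
            raise ThermogramParseError(path, line_no,
                                       f"expected {ncols} columns, got {len(fields)}")
        try:
            t.append(float(fields[0]))
            p.append(float(fields[1]) * 1e-9)
            inc.append(bool(int(fields[2])) if len(fields) > 2 else True)
        except ValueError as err:
            raise ThermogramParseError(path, line_no, str(err)) from None
    if not header_seen:
        raise ThermogramParseError(path, 1, "no header line found (empty file?)")
    if not t:
        raise ThermogramParseError(path, 1, "no data rows")
    cut = meta.get("cut_time_h", "")
    return Thermogram(
        t=np.asarray(t),
        p=np.asarray(p),
        volume_mL=float(meta.get("volume_mL", 2.0)),
        label=meta.get("label", path.stem),
        corrected=meta.get("corrected", "false").lower() in _TRUE,
        mask=np.asarray(inc, dtype=bool),
        cut_time_h=float(cut) if cut not in ("", "none", "None") else None,
    )


def write_thermogram(tg: Thermogram, path) -> Path:
    """Write a thermogram as canonical comma-separated text (power in nW)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# label: {tg.label}\n")
    buf.write(f"# volume_mL: {tg.volume_mL!r}\n")
    buf.write(f"# corrected: {str(tg.corrected).lower()}\n")
    if tg.cut_time_h is not None:
        buf.write(f"# cut_time_h: {tg.cut_time_h!r}\n")
    full_mask = bool(tg.mask.all())
    buf.write("time_h,power_nW" + ("" if full_mask else ",included") + "\n")
    for i in range(len(tg.t)):
        row = f"{tg.t[i]:.9g},{tg.p[i] * 1e9:.9g}"
        if not full_mask:
            row += f",{int(tg.mask[i])}"
        buf.write(row + "\n")
    path.write_text(buf.getvalue())
    return path


def write_param_log(path, command: str, params: Mapping) -> Path:
    """Machine-readable record of every parameter a run used."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"command": command, "params": _jsonable(params)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
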