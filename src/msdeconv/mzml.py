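"""Minimal mzML read/write support for MS1 scans.

Covers exactly what EIC extraction needs: scan start times and m/z /
intensity arrays (64- or 32-bit floats, optionally zlib-compressed,
base64-encoded).  The writer emits uncompressed 64-bit arrays that both
this reader and mainstream libraries can parse.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Scan", "read_mzml", "write_mzml"]

_NS = {"mz": "http://psi.hupo.org/ms/mzml"}

_ACC_TIME = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MINUTE = "UO:0000031"


@dataclass
class Scan:
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(binary_el, cvparams) -> np.ndarray:
    accs = {p.get("accession") for p in cvparams}
    raw = base64.b64decode((binary_el.text or "").strip())
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Scan]:
    """Parse MS1 scans (rt seconds, m/z and intensity arrays)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"unreadable mzML file {path}: {exc}") from exc
    scans: list[Scan] = []
    for spec in tree.iter():
        if _local(spec.tag) != "spectrum":
            continue
        rt = None
        arrays: dict[str, np.ndarray] = {}
        for el in spec.iter():
            if _local(el.tag) == "cvParam" and el.get("accession") == _ACC_TIME:
                rt = float(el.get("value"))
                unit = el.get("unitAccession", "")
                if unit == _ACC_MINUTE or "minute" in (el.get("unitName") or ""):
                    rt *= 60.0
        for bda in spec.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            cvs = [e for e in bda.iter() if _local(e.tag) == "cvParam"]
            accs = {c.get("accession") for c in cvs}
            binary = next(
                (e for e in bda.iter() if _local(e.tag) == "binary"), None
            )
            if binary is None:
                continue
            data = _decode_binary(binary, cvs)
            if _ACC_MZ_ARRAY in accs:
                arrays["mz"] = data
            elif _ACC_INT_ARRAY in accs:
                arrays["intensity"] = data
        if rt is None or "mz" not in arrays or "intensity" not in arrays:
            continue
        scans.append(Scan(rt=rt, mz=arrays["mz"], intensity=arrays["intensity"]))
    scans.sort(key=lambda s: s.rt)
    return scans


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{values.size}d", *values.astype(float))
    ).decode("ascii")


def write_mzml(scans: Sequence[Scan], path: str | Path) -> None:
    """Write MS1 scans as minimal mzML (uncompressed 64-bit arrays)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'<run id="run1"><spectrumList count="{len(scans)}">',
    ]
    for i, scan in enumerate(scans):
        mz = np.asarray(scan.mz, dtype=float)
        inten = np.asarray(scan.intensity, dtype=float)
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{mz.size}">'
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            "<scanList count=\"1\"><scan>"
            f'<cvParam cvRef="MS" accession="{_ACC_TIME}" name="scan start time" '
            f'value="{scan.rt}" unitAccession="UO:0000010" unitName="second"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="0">'
            f'<cvParam cvRef="MS" accession="{_ACC_64BIT}" name="64-bit float"/>'
            f'<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            f'<cvParam cvRef="MS" accession="{_ACC_MZ_ARRAY}" name="m/z array"/>'
            f"<binary>{_b64(mz)}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="0">'
            f'<cvParam cvRef="MS" accession="{_ACC_64BIT}" name="64-bit float"/>'
            f'<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            f'<cvParam cvRef="MS" accession="{_ACC_INT_ARRAY}" name="intensity array"/>'
            f"<binary>{_b64(inten)}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    parts.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(parts))
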