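"""Peak-table readers/writers, annotated exports and EIC extraction.

Peak tables follow the XCMS column dialect (mz, rt, rtmin, rtmax, maxo,
into, intb, sample).  Annotated peak-list exports carry the input columns
plus isotope / adduct / pseudo-spectrum-group columns and a ``c13_partner``
column linking 12C and 13C monoisotopic peaks.  Molecule lists report one
row per confirmed metabolite and sample with normalized abundances and
12C/13C quotients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mzml import read_mzml
from .pipeline import (
    EIC,
    DeconvolutionResult,
    LabelPair,
    Peak,
    PseudoSpectrum,
    PeakAnnotation,
)
from .quant import AbundanceRecord, isotopomer_ratio

__all__ = [
    "PeakTableDialect",
    "read_peak_table",
    "write_peak_table",
    "extract_eics",
    "write_peak_list",
    "write_molecule_list",
    "result_to_dict",
    "save_result",
    "load_result",
]


@dataclass(frozen=True)
class PeakTableDialect:
    mz: str = "mz"
    rt: str = "rt"
    rtmin: str = "rtmin"
    rtmax: str = "rtmax"
    maxo: str = "maxo"
    into: str = "into"
    intb: str = "intb"
    sample: str = "sample"
    id_col: str = "peak_id"
    delimiter: str | None = None  # None = infer from extension

    @property
    def required(self) -> tuple[str, ...]:
        return (self.mz, self.rt)


def _sep_for(path: Path, dialect: PeakTableDialect) -> str:
    if dialect.delimiter:
        return dialect.delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_peak_table(
    path: str | Path, dialect: PeakTableDialect | None = None
) -> list[Peak]:
    """Read one chromatogram's peak table; one Peak per row, ids stable in
    row order (or taken from the id column when present)."""
    dialect = dialect or PeakTableDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    for col in dialect.required:
        if col not in df.columns:
            raise ValueError(f"peak table {path} lacks required column {col!r}")
    abundance_cols = [
        c for c in (dialect.maxo, dialect.into, dialect.intb) if c in df.columns
    ]
    if not abundance_cols:
        raise ValueError(
            f"peak table {path} lacks an abundance column "
            f"({dialect.maxo}/{dialect.into}/{dialect.intb})"
        )
    numeric = [dialect.mz, dialect.rt] + [
        c for c in (dialect.rtmin, dialect.rtmax) if c in df.columns
    ] + abundance_cols
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {col!r}, row {int(bad[0])}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = vals
    peaks: list[Peak] = []
    for i, row in df.iterrows():
        pid = (
            str(row[dialect.id_col])
            if dialect.id_col in df.columns
            else f"p{i + 1:04d}"
        )
        rt = float(row[dialect.rt])
        get = lambda c, d: float(row[c]) if c in df.columns and pd.notna(row[c]) else d
        maxo = get(dialect.maxo, 0.0)
        into = get(dialect.into, 0.0)
        peaks.append(
            Peak(
                id=pid,
                mz=float(row[dialect.mz]),
                rt=rt,
                rt_min=get(dialect.rtmin, rt),
                rt_max=get(dialect.rtmax, rt),
                maxo=maxo,
                into=into,
                intb=get(dialect.intb, into),
                sample=str(row[dialect.sample])
                if dialect.sample in df.columns
                else "s1",
            )
        )
    return peaks


def write_peak_table(
    peaks: Sequence[Peak], path: str | Path, dialect: PeakTableDialect | None = None
) -> None:
    """Inverse of :func:`read_peak_table` (numeric round trip to 1e-9)."""
    dialect = dialect or PeakTableDialect()
    path = Path(path)
    df = pd.DataFrame(
        {
            dialect.id_col: [p.id for p in peaks],
            dialect.mz: [p.mz for p in peaks],
            dialect.rt: [p.rt for p in peaks],
            dialect.rtmin: [p.rt_min for p in peaks],
            dialect.rtmax: [p.rt_max for p in peaks],
            dialect.maxo: [p.maxo for p in peaks],
            dialect.into: [p.into for p in peaks],
            dialect.intb: [p.intb for p in peaks],
            dialect.sample: [p.sample for p in peaks],
        }
    )
    df.to_csv(path, sep=_sep_for(path, dialect), index=False)


# ----------------------------------------------------------------------
# EIC extraction from raw chromatograms
# ----------------------------------------------------------------------

def extract_eics(
    mzml_path: str | Path,
    peaks: Sequence[Peak],
    mz_halfwidth: float = 0.01,
    rt_pad: float = 10.0,
) -> list[str]:
    """Attach EIC traces in place by summing signal within ``mz_halfwidth``
    of each peak's m/z over [rt_min - pad, rt_max + pad].  Returns ids of
    peaks whose window contained no scans (flagged with an empty trace)."""
    scans = read_mzml(mzml_path)
    rts = np.array([s.rt for s in scans])
    empty: list[str] = []
    for p in peaks:
        lo, hi = p.rt_min - rt_pad, p.rt_max + rt_pad
        idx = np.where((rts >= lo) & (rts <= hi))[0]
        if idx.size == 0:
            p.eic = EIC(rt=np.array([]), intensity=np.array([]))
            empty.append(p.id)
            continue
        trace = np.empty(idx.size)
        for k, i in enumerate(idx):
            s = scans[i]
            sel = np.abs(s.mz - p.mz) <= mz_halfwidth
            trace[k] = float(s.intensity[sel].sum())
        p.eic = EIC(rt=rts[idx], intensity=trace)
    return empty


# ----------------------------------------------------------------------
# annotated exports
# ----------------------------------------------------------------------

def _write_frame(df: pd.DataFrame, path: Path, fmt: str | None) -> None:
    fmt = fmt or {".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower(), "csv")
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def write_peak_list(
    peaks: Sequence[Peak],
    result: DeconvolutionResult,
    path: str | Path,
    fmt: str | None = None,
) -> pd.DataFrame:
    """One row per peak: input columns + isotopes, adduct labels, pseudo-
    spectrum group ids, multi-assignment flag and the 12C/13C association
    column ``c13_partner``."""
    path = Path(path)
    iso: dict[str, str] = {}
    for ch in result.chains:
        tag = "13C" if ch.mirrored else "12C"
        for k, pid in enumerate(ch.members):
            step = -k if ch.mirrored else k
            iso[pid] = f"[{tag} M{step:+d}][z={ch.charge}]" if k else f"[{tag} M][z={ch.charge}]"
    labels: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    for spec in result.spectra:
        for a in spec.annotations:
            labels.setdefault(a.peak, []).append(a.ion_label)
            g = groups.setdefault(a.peak, [])
            if spec.id not in g:
                g.append(spec.id)
    partner: dict[str, str] = {}
    for lp in result.label_pairs:
        partner[lp.c12_peak] = lp.c13_peak
        partner[lp.c13_peak] = lp.c12_peak
    rows = []
    for p in peaks:
        rows.append(
            {
                "peak_id": p.id,
                "mz": p.mz,
                "rt": p.rt,
                "rtmin": p.rt_min,
                "rtmax": p.rt_max,
                "maxo": p.maxo,
                "into": p.into,
                "intb": p.intb,
                "sample": p.sample,
                "isotopes": iso.get(p.id, ""),
                "adduct": ";".join(labels.get(p.id, [])),
                "pseudospectrum": ";".join(groups.get(p.id, [])),
                "multi_assigned": len(groups.get(p.id, [])) > 1,
                "c13_partner": partner.get(p.id, ""),
            }
        )
    df = pd.DataFrame(rows)
    _write_frame(df, path, fmt)
    return df


_MOLECULE_COLUMNS = [
    "compound",
    "spectrum_id",
    "M",
    "rt",
    "sample",
    "ion_label",
    "adducts",
    "abundance",
    "normalized_abundance",
    "c13_abundance",
    "ratio",
]


def write_molecule_list(
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    label_pairs: Sequence[LabelPair],
    path: str | Path,
    fmt: str | None = None,
    normalizers: dict[str, float] | None = None,
    abundance_kind: str = "area",
) -> pd.DataFrame:
    """Confirmed / manually annotated metabolites, one row per spectrum and
    sample, with the uniform adduct inventory and 12C/13C quotients where
    the labeled standard was detected."""
    path = Path(path)
    by_id = {p.id: p for p in peaks}
    partner = {lp.c12_peak: lp.c13_peak for lp in label_pairs}
    attr = {"intensity": "maxo", "area": "into", "baseline_corrected_area": "intb"}[
        abundance_kind
    ]
    rows = []
    for spec in spectra:
        if spec.status not in ("confirmed", "manual"):
            continue
        prim = spec.primary()
        if prim is None or prim.peak not in by_id:
            continue
        p = by_id[prim.peak]
        norm = (normalizers or {}).get(p.sample, 1.0)
        c13 = by_id.get(partner.get(prim.peak, ""), None)
        rec = AbundanceRecord(
            spectrum_id=spec.id,
            ion_label=prim.ion_label,
            c12_abundance=getattr(p, attr),
            c13_abundance=getattr(c13, attr) if c13 is not None else None,
            abundance_kind=abundance_kind,
            normalizer=norm,
            sample=p.sample,
        )
        rr = isotopomer_ratio(rec)
        adducts = sorted(
            {
                a.ion_label
                for a in spec.annotations
                if a.role in ("seed_adduct", "adduct", "fragment", "homoadduct")
            }
        )
        rows.append(
            {
                "compound": spec.compound_name or "",
                "spectrum_id": spec.id,
                "M": spec.M,
                "rt": spec.rt,
                "sample": p.sample,
                "ion_label": prim.ion_label,
                "adducts": ";".join(adducts),
                "abundance": getattr(p, attr),
                "normalized_abundance": rr.normalized_c12,
                "c13_abundance": getattr(c13, attr) if c13 is not None else np.nan,
                "ratio": rr.ratio if rr.ratio is not None else np.nan,
            }
        )
    df = pd.DataFrame(rows, columns=_MOLECULE_COLUMNS)
    _write_frame(df, path, fmt)
    return df


# ----------------------------------------------------------------------
# deconvolution-result JSON
# ----------------------------------------------------------------------

def result_to_dict(result: DeconvolutionResult) -> dict:
    return {
        "format": "msdeconv-result",
        "version": 1,
        "spectra": [
            {
                "id": s.id,
                "M": s.M,
                "rt": s.rt,
                "status": s.status,
                "compound": s.compound_name,
                "annotations": [
                    {
                        "peak": a.peak,
                        "label": a.ion_label,
                        "role": a.role,
                        "shift": a.shift,
                        "loss": a.loss_formula.hill() if a.loss_formula else None,
                        "ambiguous": a.ambiguous,
                        "unverified": a.unverified,
                    }
                    for a in s.annotations
                ],
            }
            for s in result.spectra
        ],
        "chains": [
            {
                "monoisotopic": c.monoisotopic_peak,
                "members": c.members,
                "charge": c.charge,
                "mirrored": c.mirrored,
            }
            for c in result.chains
        ],
        "label_pairs": [
            {"c12": lp.c12_peak, "c13": lp.c13_peak, "n": lp.n}
            for lp in result.label_pairs
        ],
        "orphans": list(result.orphans),
    }


def save_result(result: DeconvolutionResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=1))


def load_result(path: str | Path) -> DeconvolutionResult:
    from .chem import parse_formula
    from .pipeline import IsotopeChain

    d = json.loads(Path(path).read_text())
    spectra = []
    for s in d.get("spectra", []):
        spec = PseudoSpectrum(
            M=s["M"],
            rt=s["rt"],
            status=s.get("status", "auto"),
            compound_name=s.get("compound"),
            id=s["id"],
            annotations=[
                PeakAnnotation(
                    peak=a["peak"],
                    ion_label=a["label"],
                    role=a["role"],
                    shift=a.get("shift", 0),
                    loss_formula=parse_formula(a["loss"]) if a.get("loss") else None,
                    ambiguous=a.get("ambiguous", False),
                    unverified=a.get("unverified", False),
                )
                for a in s.get("annotations", [])
            ],
        )
        spectra.append(spec)
    chains = [
        IsotopeChain(c["monoisotopic"], c["members"], c["charge"], c["mirrored"])
        for c in d.get("chains", [])
    ]
    pairs = [
        LabelPair(c["c12"], c["c13"], c["n"]) for c in d.get("label_pairs", [])
    ]
    return DeconvolutionResult(spectra, chains, pairs, d.get("orphans", []))
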