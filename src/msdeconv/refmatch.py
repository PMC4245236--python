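"""Reference-spectrum lists, pseudo fragment spectra and dot-product search.

A reference list stores curated pseudo spectra (12C member peaks with
relative intensities and ion labels) for reuse on later chromatograms.
Similarity is plain cosine over greedily m/z-paired peaks; local spectral
record files in the MassBank text format (``PK$PEAK`` block) can be searched
with the same score.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .pipeline import Peak, PeakAnnotation, PseudoSpectrum, SDConfig

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumPeak",
    "ReferenceSpectrum",
    "ReferenceList",
    "dot_product_score",
    "pseudo_fragment_spectrum",
    "create_reference_list",
    "apply_reference_list",
    "match_record_file",
    "parse_massbank_record",
]

#: (m/z, relative intensity in [0, 1], ion label or "")
SpectrumPeak = tuple[float, float, str]


def _normalized(peaks: Sequence[tuple]) -> list[SpectrumPeak]:
    if not peaks:
        raise ValueError("spectrum must contain at least one peak")
    top = max(p[1] for p in peaks)
    if top <= 0:
        raise ValueError("spectrum has no positive intensity")
    return [
        (float(p[0]), float(p[1]) / top, str(p[2]) if len(p) > 2 else "")
        for p in peaks
    ]


@dataclass
class ReferenceSpectrum:
    compound: str
    M: float
    rt: float
    peaks: list[SpectrumPeak]

    def __post_init__(self):
        self.peaks = _normalized(self.peaks)


@dataclass
class ReferenceList:
    name: str
    entries: list[ReferenceSpectrum] = field(default_factory=list)
    method: str = ""
    score_threshold: float = 0.8
    rt_tolerance: float = 10.0
    version: int = 1

    def __post_init__(self):
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "msdeconv-reference-list",
            "version": self.version,
            "name": self.name,
            "method": self.method,
            "score_threshold": self.score_threshold,
            "rt_tolerance": self.rt_tolerance,
            "entries": [
                {
                    "compound": e.compound,
                    "M": e.M,
                    "rt": e.rt,
                    "peaks": [list(p) for p in e.peaks],
                }
                for e in self.entries
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceList":
        d = json.loads(Path(path).read_text())
        return cls(
            name=d["name"],
            method=d.get("method", ""),
            score_threshold=d.get("score_threshold", 0.8),
            rt_tolerance=d.get("rt_tolerance", 10.0),
            version=d.get("version", 1),
            entries=[
                ReferenceSpectrum(
                    compound=e["compound"],
                    M=e["M"],
                    rt=e["rt"],
                    peaks=[tuple(p) for p in e["peaks"]],
                )
                for e in d.get("entries", [])
            ],
        )


def dot_product_score(
    a: Sequence[tuple], b: Sequence[tuple], mz_tol: float = 0.01
) -> float:
    """Cosine similarity after greedy nearest-m/z pairing within ``mz_tol``.

    Unpaired peaks contribute zero to the cross term but full weight to the
    norms.  Symmetric; 1.0 for identical spectra.
    """
    pa = _normalized(a)
    pb = _normalized(b)
    cands = []
    for i, (mza, ia, _) in enumerate(pa):
        for j, (mzb, ib, _) in enumerate(pb):
            d = abs(mza - mzb)
            if d <= mz_tol:
                cands.append((d, i, j))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    cross = 0.0
    for d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        cross += pa[i][1] * pb[j][1]
    norm_a = math.sqrt(sum(p[1] ** 2 for p in pa))
    norm_b = math.sqrt(sum(p[1] ** 2 for p in pb))
    return cross / (norm_a * norm_b)


_C12_ROLES = ("seed_adduct", "adduct", "fragment", "homoadduct")


def _c12_peaks(
    spec: PseudoSpectrum, peaks_by_id: dict[str, Peak]
) -> list[SpectrumPeak]:
    out = []
    for a in spec.annotations:
        if a.role in _C12_ROLES and a.shift == 0 and a.peak in peaks_by_id:
            p = peaks_by_id[a.peak]
            out.append((p.mz, p.intensity, a.ion_label))
    return out


def pseudo_fragment_spectrum(
    spec: PseudoSpectrum, peaks_by_id: dict[str, Peak]
) -> list[SpectrumPeak]:
    """The pseudo-molecular ion plus all fragment members; other adducts,
    homoadducts, isotopes and 13C peaks are excluded."""
    pm = None
    for a in spec.annotations:
        if a.ion_label in ("[M+H]+", "[M-H]-") and a.role == "seed_adduct":
            pm = a
            break
    if pm is None:
        raise ValueError(
            f"spectrum {spec.id} has no pseudo-molecular ion ([M+H]+ / [M-H]-)"
        )
    chosen = [pm] + [a for a in spec.annotations if a.role == "fragment" and a.shift == 0]
    raw = [
        (peaks_by_id[a.peak].mz, peaks_by_id[a.peak].intensity, a.ion_label)
        for a in chosen
        if a.peak in peaks_by_id
    ]
    return _normalized(raw)


def create_reference_list(
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    name: str = "reference",
    method: str = "",
    score_threshold: float = 0.8,
    rt_tolerance: float = 10.0,
) -> ReferenceList:
    """Store confirmed / manually annotated pseudo spectra as reference
    entries (12C members only); unconfirmed spectra are skipped with a
    warning."""
    by_id = {p.id: p for p in peaks}
    entries = []
    for spec in spectra:
        if spec.status not in ("confirmed", "manual") or not spec.compound_name:
            logger.warning("skipping unconfirmed spectrum %s", spec.id)
            continue
        pk = _c12_peaks(spec, by_id)
        if not pk:
            logger.warning("spectrum %s has no 12C member peaks", spec.id)
            continue
        entries.append(
            ReferenceSpectrum(
                compound=spec.compound_name, M=spec.M, rt=spec.rt, peaks=pk
            )
        )
    return ReferenceList(
        name=name,
        method=method,
        entries=entries,
        score_threshold=score_threshold,
        rt_tolerance=rt_tolerance,
    )


def apply_reference_list(
    ref: ReferenceList,
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    cfg: SDConfig | None = None,
    mz_tol: float = 0.01,
) -> list[dict]:
    """Annotate the best-matching pseudo spectrum for each reference entry
    (dot product >= threshold within the RT tolerance).  When no deconvolved
    spectrum matches, peaks matching the entry's m/z pattern are assembled
    into a new confirmed spectrum (appended to ``spectra`` if it is a list).
    """
    cfg = cfg or SDConfig()
    by_id = {p.id: p for p in peaks}
    results: list[dict] = []
    for entry in ref.entries:
        best_spec = None
        best_score = -1.0
        for spec in spectra:
            if abs(spec.rt - entry.rt) > ref.rt_tolerance:
                continue
            pk = _c12_peaks(spec, by_id)
            if not pk:
                continue
            score = dot_product_score(entry.peaks, pk, mz_tol)
            if score > best_score:
                best_score, best_spec = score, spec
        if best_spec is not None and best_score >= ref.score_threshold:
            best_spec.compound_name = entry.compound
            best_spec.status = "confirmed"
            results.append(
                {"compound": entry.compound, "spectrum": best_spec.id,
                 "score": best_score, "assembled": False}
            )
            continue
        # assembly mode: collect peaks matching the entry's pattern
        anns: list[PeakAnnotation] = []
        hits = []
        for mz, inten, label in entry.peaks:
            cand = [
                p
                for p in peaks
                if abs(p.mz - mz) <= cfg.eps_mz
                and abs(p.rt - entry.rt) <= ref.rt_tolerance
            ]
            if not cand:
                continue
            cand.sort(key=lambda p: (abs(p.mz - mz), p.id))
            hits.append((cand[0], inten, label))
        if not hits:
            results.append(
                {"compound": entry.compound, "spectrum": None,
                 "score": best_score if best_score >= 0 else None,
                 "assembled": False}
            )
            continue
        score = dot_product_score(
            entry.peaks, [(p.mz, p.intensity, l) for p, _, l in hits], mz_tol
        )
        if score < ref.score_threshold:
            results.append(
                {"compound": entry.compound, "spectrum": None, "score": score,
                 "assembled": False}
            )
            continue
        for p, _, label in hits:
            role = "seed_adduct" if label in ("[M+H]+", "[M-H]-", "[M+Na]+", "[M+K]+") else "adduct"
            anns.append(PeakAnnotation(peak=p.id, ion_label=label, role=role))
        new = PseudoSpectrum(
            M=entry.M,
            rt=entry.rt,
            annotations=anns,
            status="confirmed",
            compound_name=entry.compound,
        )
        if isinstance(spectra, list):
            spectra.append(new)
        results.append(
            {"compound": entry.compound, "spectrum": new.id, "score": score,
             "assembled": True}
        )
    return results


# ----------------------------------------------------------------------
# local spectral record files (MassBank text format)
# ----------------------------------------------------------------------

def parse_massbank_record(path: str | Path) -> tuple[str, list[SpectrumPeak]]:
    """Read one record file; returns (record name, normalized peak list).

    Only the ``PK$PEAK`` block (``m/z int. rel.int.`` lines) and a few
    header fields are consumed.
    """
    name = Path(path).stem
    peaks: list[tuple[float, float, str]] = []
    in_block = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("RECORD_TITLE:"):
            name = line.split(":", 1)[1].strip() or name
        elif line.startswith("CH$NAME:") and name == Path(path).stem:
            name = line.split(":", 1)[1].strip() or name
        if line.startswith("PK$PEAK:"):
            in_block = True
            continue
        if in_block:
            if not line.strip() or line.startswith("//") or line.startswith("PK$"):
                break
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed peak line in {path}: {line!r}")
            mz = float(parts[0])
            inten = float(parts[2]) if len(parts) >= 3 else float(parts[1])
            peaks.append((mz, inten, ""))
    if not peaks:
        raise ValueError(f"no PK$PEAK block found in {path}")
    return name, _normalized(peaks)


def match_record_file(
    query: Sequence[tuple],
    record_paths: Iterable[str | Path],
    mz_tol: float = 0.01,
) -> list[tuple[str, float]]:
    """Score the query spectrum against each local record, ranked by
    descending dot product; unparseable records are skipped with a warning."""
    out: list[tuple[str, float]] = []
    for path in record_paths:
        try:
            name, peaks = parse_massbank_record(path)
        except (ValueError, OSError) as exc:
            logger.warning("skipping record %s: %s", path, exc)
            continue
        out.append((name, dot_product_score(query, peaks, mz_tol)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
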