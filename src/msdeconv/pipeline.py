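"""Seven-step deconvolution of one chromatogram's peak table.

Steps: (1) peaks are parsed upstream (:mod:`msdeconv.io`); (2) isotope-chain
detection, including "mirrored" chains descending from fully-13C-labeled
monoisotopic peaks; (3) pseudo-spectrum assembly from seed-adduct m/z
distances; (4) association of 13C monoisotopic peaks with their 12C
counterparts; (5) homoadduct annotation, including mixed-label shifts like
``[2M+5+H]+``; (6) annotation of large uncommon neutral losses via
constrained sum-formula triplets ``s_p = s_f + s_l``; (7) pruning of members
whose EIC correlation to the primary peak is below a threshold.

Curation helpers (:func:`claim_peaks`, :func:`list_orphans`,
:func:`find_correlating_peaks`) operate on the assembled result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .chem import (
    C13_DELTA,
    PROTON_MASS,
    Formula,
    IonSpeciesDef,
    default_ion_list,
    ion_mz,
    neutral_mass_from_mz,
)
from .decomp import (
    CHEMISTRY_FILTERS,
    DecompositionQuery,
    ElementBounds,
    carbon_count_range,
    decompose,
    default_bounds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EIC",
    "Peak",
    "IsotopeChain",
    "LabelPair",
    "PeakAnnotation",
    "PseudoSpectrum",
    "SDConfig",
    "DeconvolutionResult",
    "CorrelationUnavailable",
    "deconvolve",
    "detect_isotope_chains",
    "assemble_pseudo_spectra",
    "associate_label_pairs",
    "detect_homoadducts",
    "annotate_uncommon_losses",
    "eic_correlation",
    "prune_by_correlation",
    "claim_peaks",
    "list_orphans",
    "find_correlating_peaks",
]


@dataclass(frozen=True)
class EIC:
    """Extracted ion chromatogram: paired rt / intensity arrays."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if rt.shape != inten.shape:
            raise ValueError("rt and intensity arrays must have equal length")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)

    @property
    def empty(self) -> bool:
        return self.rt.size == 0


@dataclass
class Peak:
    """One detected LC-MS feature."""

    id: str
    mz: float
    rt: float
    rt_min: float | None = None
    rt_max: float | None = None
    maxo: float = 0.0
    into: float = 0.0
    intb: float = 0.0
    sample: str = "s1"
    eic: EIC | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak {self.id}: m/z must be positive")
        if self.rt_min is None:
            self.rt_min = self.rt
        if self.rt_max is None:
            self.rt_max = self.rt
        if not (self.rt_min <= self.rt <= self.rt_max):
            raise ValueError(f"peak {self.id}: rt outside [rt_min, rt_max]")
        for attr in ("maxo", "into", "intb"):
            if getattr(self, attr) < 0:
                raise ValueError(f"peak {self.id}: negative {attr}")

    @property
    def intensity(self) -> float:
        return self.maxo


@dataclass
class IsotopeChain:
    """Isotopologue series; member 0 is the monoisotopic peak.

    For ``mirrored`` chains the members extend toward *lower* m/z from a
    13C monoisotopic peak.
    """

    monoisotopic_peak: str
    members: list[str]
    charge: int
    mirrored: bool = False


@dataclass(frozen=True)
class LabelPair:
    """12C monoisotopic peak paired with its fully-13C counterpart."""

    c12_peak: str
    c13_peak: str
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("carbon count n must be a positive integer")


@dataclass
class PeakAnnotation:
    peak: str
    ion_label: str
    role: str  # seed_adduct | adduct | fragment | homoadduct | isotope | c13_monoisotopic | c13_isotope
    species: IonSpeciesDef | None = None
    shift: int = 0
    loss_formula: Formula | None = None
    ambiguous: bool = False
    unverified: bool = False


_ROLES = {
    "seed_adduct",
    "adduct",
    "fragment",
    "homoadduct",
    "isotope",
    "c13_monoisotopic",
    "c13_isotope",
}


@dataclass
class PseudoSpectrum:
    """A putative neutral mass M with its annotated member peaks."""

    M: float
    rt: float
    annotations: list[PeakAnnotation] = field(default_factory=list)
    status: str = "auto"  # auto | confirmed | manual
    compound_name: str | None = None
    id: str = ""

    def __post_init__(self):
        if not self.id:
            self.id = f"M{self.M:.3f}T{self.rt:.2f}"

    def member_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.annotations:
            if a.peak not in seen:
                seen.append(a.peak)
        return seen

    def annotations_for(self, peak_id: str) -> list[PeakAnnotation]:
        return [a for a in self.annotations if a.peak == peak_id]

    def primary(self) -> PeakAnnotation | None:
        """The pseudo-molecular ion if present, else the first seed adduct."""
        for label in ("[M+H]+", "[M-H]-"):
            for a in self.annotations:
                if a.ion_label == label and a.role == "seed_adduct":
                    return a
        for a in self.annotations:
            if a.role == "seed_adduct":
                return a
        return None


@dataclass
class SDConfig:
    """Tunables of the deconvolution pipeline."""

    eps_rt: float = 5.0
    eps_mz: float = 0.005
    labeled: bool = True
    correlation_threshold: float = 0.85
    max_isotopes: int = 4
    ion_list: list[IonSpeciesDef] = field(default_factory=default_ion_list)
    bounds: ElementBounds = field(default_factory=default_bounds)
    decomp_tolerance: float = 0.005
    mode: str = "positive"
    intensity_slack: float = 1.05  # tolerated ratio for the "decreasing" rule

    def __post_init__(self):
        if self.eps_rt <= 0 or self.eps_mz <= 0:
            raise ValueError("eps_rt and eps_mz must be positive")
        if not (0.0 <= self.correlation_threshold <= 1.0):
            raise ValueError("correlation_threshold must be within [0, 1]")
        if self.max_isotopes < 2:
            raise ValueError("max_isotopes must be >= 2")


@dataclass
class DeconvolutionResult:
    spectra: list[PseudoSpectrum]
    chains: list[IsotopeChain]
    label_pairs: list[LabelPair]
    orphans: list[str]


class CorrelationUnavailable(Exception):
    """EIC correlation cannot be computed (missing traces or no overlap)."""


# ----------------------------------------------------------------------
# step 2: isotope chains
# ----------------------------------------------------------------------

def detect_isotope_chains(peaks: Sequence[Peak], cfg: SDConfig) -> list[IsotopeChain]:
    """Forward chains (natural patterns, intensity decreasing with m/z) and,
    when ``cfg.labeled``, mirrored chains descending from 13C monoisotopic
    candidates.  A peak joins at most one chain per direction."""
    by_id = {p.id: p for p in peaks}
    order = sorted(peaks, key=lambda p: (p.mz, p.id))
    mzs = np.array([p.mz for p in order])

    def candidates(target_mz: float, ref: Peak) -> list[Peak]:
        lo = np.searchsorted(mzs, target_mz - cfg.eps_mz)
        hi = np.searchsorted(mzs, target_mz + cfg.eps_mz)
        out = [
            order[i]
            for i in range(lo, hi)
            if abs(order[i].rt - ref.rt) <= cfg.eps_rt and order[i].id != ref.id
        ]
        out.sort(key=lambda p: (abs(p.mz - target_mz), p.id))
        return out

    chains: list[IsotopeChain] = []
    taken: set[str] = set()  # non-monoisotopic members of forward chains
    for p in order:
        if p.id in taken:
            continue
        for z in (1, 2):
            members = [p]
            for k in range(1, cfg.max_isotopes):
                target = p.mz + k * C13_DELTA / z
                nxt = None
                for c in candidates(target, p):
                    if c.id in taken or c.id == p.id:
                        continue
                    if c.intensity < members[-1].intensity * cfg.intensity_slack:
                        nxt = c
                        break
                if nxt is None:
                    break
                members.append(nxt)
            if len(members) >= 2:
                chains.append(
                    IsotopeChain(p.id, [m.id for m in members], charge=z)
                )
                taken.update(m.id for m in members[1:])
                break

    if cfg.labeled:
        mirror_taken: set[str] = set()
        forward_members = set(taken)
        for p in sorted(peaks, key=lambda q: (-q.mz, q.id)):
            if p.id in mirror_taken or p.id in forward_members:
                continue
            for z in (1, 2):
                members = [p]
                for k in range(1, cfg.max_isotopes):
                    target = p.mz - k * C13_DELTA / z
                    nxt = None
                    for c in candidates(target, p):
                        if c.id in mirror_taken or c.id in forward_members:
                            continue
                        if c.intensity < members[-1].intensity * cfg.intensity_slack:
                            nxt = c
                            break
                    if nxt is None:
                        break
                    members.append(nxt)
                if len(members) >= 2:
                    chains.append(
                        IsotopeChain(
                            p.id, [m.id for m in members], charge=z, mirrored=True
                        )
                    )
                    mirror_taken.update(m.id for m in members)
                    break
    return chains


def _chain_index(chains: Iterable[IsotopeChain]):
    fwd_mono: dict[str, IsotopeChain] = {}
    fwd_member: set[str] = set()
    mir_mono: dict[str, IsotopeChain] = {}
    mir_member: set[str] = set()
    for ch in chains:
        if ch.mirrored:
            mir_mono[ch.monoisotopic_peak] = ch
            mir_member.update(ch.members[1:])
        else:
            fwd_mono[ch.monoisotopic_peak] = ch
            fwd_member.update(ch.members[1:])
    return fwd_mono, fwd_member, mir_mono, mir_member


def _shifted_label(label: str, n: int) -> str:
    """Insert a labeling shift into an ion label: [M+H]+ -> [M+5+H]+,
    [2M+H]+ -> [2M+5+H]+, [M+H-H2O]+ -> [M+5+H-H2O]+."""
    for head in ("[2M", "[M"):
        if label.startswith(head):
            return f"{head}+{n}" + label[len(head):]
    return f"{label}+{n}"


# ----------------------------------------------------------------------
# step 3: pseudo-spectrum assembly
# ----------------------------------------------------------------------

def assemble_pseudo_spectra(
    peaks: Sequence[Peak], chains: Sequence[IsotopeChain], cfg: SDConfig
) -> list[PseudoSpectrum]:
    """Pair monoisotopic 12C peaks whose m/z distance matches a seed-adduct
    to any listed single-M species, then group matched pairs by the implied
    neutral mass M.  Isotopologues of members are attached.  A peak may end
    up in several pseudo spectra (resolved later by :func:`claim_peaks`)."""
    by_id = {p.id: p for p in peaks}
    fwd_mono, fwd_member, mir_mono, mir_member = _chain_index(chains)
    charge_of = {pid: ch.charge for pid, ch in fwd_mono.items()}

    mono12 = [
        p
        for p in peaks
        if p.id not in fwd_member
        and p.id not in mir_member
        and p.id not in mir_mono  # 13C monoisotopic candidates are not 12C
    ]
    mono12.sort(key=lambda p: (p.mz, p.id))

    species = [s for s in cfg.ion_list if s.multiplicity == 1 and s.mode == cfg.mode]
    seeds = [s for s in species if s.is_seed]
    sp_index = {s.label: i for i, s in enumerate(cfg.ion_list)}

    # accumulating spectra: list of dicts {M values, rt, annotations by (peak,label)}
    groups: list[dict] = []

    def add_match(Mval: float, rt: float, items: list[tuple[Peak, IonSpeciesDef]]):
        for g in groups:
            if abs(g["M"] - Mval) <= cfg.eps_mz and abs(g["rt"] - rt) <= cfg.eps_rt:
                break
        else:
            g = {"M": Mval, "rt": rt, "Ms": [], "ann": {}}
            groups.append(g)
        for peak, sp in items:
            key = (peak.id, sp.label)
            if key not in g["ann"]:
                g["ann"][key] = (peak, sp)
                g["Ms"].append(neutral_mass_from_mz(peak.mz, sp))
                g["M"] = float(np.mean(g["Ms"]))

    for i, p in enumerate(mono12):
        zp = charge_of.get(p.id, 1)
        for q in mono12:
            if q.id == p.id or abs(q.rt - p.rt) > cfg.eps_rt:
                continue
            zq = charge_of.get(q.id, 1)
            for s in seeds:
                if abs(s.charge) != zp:
                    continue
                try:
                    M1 = neutral_mass_from_mz(p.mz, s)
                except ValueError:
                    continue
                for t in species:
                    if t.label == s.label and q.mz == p.mz:
                        continue
                    if abs(t.charge) != zq:
                        continue
                    try:
                        M2 = neutral_mass_from_mz(q.mz, t)
                    except ValueError:
                        continue
                    if abs(M1 - M2) <= cfg.eps_mz:
                        add_match(M1, p.rt, [(p, s), (q, t)])

    spectra: list[PseudoSpectrum] = []
    for g in sorted(groups, key=lambda g: (g["M"], g["rt"])):
        anns: list[PeakAnnotation] = []
        # one species per peak within a spectrum: first in ion-list order
        # wins, extra matches mark the annotation ambiguous
        per_peak: dict[str, list[tuple[Peak, IonSpeciesDef]]] = {}
        for (pid, _), (peak, sp) in g["ann"].items():
            per_peak.setdefault(pid, []).append((peak, sp))
        for pid in sorted(per_peak, key=lambda pid: (by_id[pid].mz, pid)):
            matches = sorted(
                per_peak[pid], key=lambda t: sp_index.get(t[1].label, 99)
            )
            peak, sp = matches[0]
            role = (
                "seed_adduct"
                if sp.is_seed
                else ("fragment" if sp.loss_formula is not None else "adduct")
            )
            anns.append(
                PeakAnnotation(
                    peak=pid,
                    ion_label=sp.label,
                    role=role,
                    species=sp,
                    ambiguous=len(matches) > 1,
                )
            )
            chain = fwd_mono.get(pid)
            if chain:
                for k, mid in enumerate(chain.members[1:], start=1):
                    anns.append(
                        PeakAnnotation(
                            peak=mid,
                            ion_label=f"{sp.label} (+{k})",
                            role="isotope",
                            species=sp,
                            shift=k,
                        )
                    )
        if not any(a.role == "seed_adduct" for a in anns):
            continue
        spec = PseudoSpectrum(M=g["M"], rt=g["rt"], annotations=anns)
        prim = spec.primary()
        if prim is not None:
            spec.rt = by_id[prim.peak].rt
            spec.id = f"M{spec.M:.3f}T{spec.rt:.2f}"
        spectra.append(spec)
    return spectra


# ----------------------------------------------------------------------
# step 4: 13C pair association
# ----------------------------------------------------------------------

def _allowed_carbons(
    ann: PeakAnnotation, M: float, cfg: SDConfig
) -> set[int]:
    """Plausible carbon counts of the *ion* behind an annotation, from mass
    decomposition of M corrected for carbons lost in a predefined loss."""
    sp = ann.species
    if sp is None:
        return set()
    base = carbon_count_range(
        M * sp.multiplicity, cfg.decomp_tolerance, cfg.bounds
    )
    loss_c = sp.loss_formula.get("C") if sp.loss_formula is not None else 0
    return {c * sp.multiplicity - loss_c for c in base if c * sp.multiplicity - loss_c >= 1}


def associate_label_pairs(
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    chains: Sequence[IsotopeChain],
    cfg: SDConfig,
) -> list[LabelPair]:
    """Pair annotated 12C monoisotopic members with identified 13C
    monoisotopic peaks (mirrored-chain anchors) at a distance of
    ``n * 1.003355 / z`` where n lies in the decomposition carbon range."""
    if not cfg.labeled:
        return []
    by_id = {p.id: p for p in peaks}
    _, fwd_member, mir_mono, mir_member = _chain_index(chains)
    annotated = {
        a.peak for s in spectra for a in s.annotations if not a.role.startswith("c13")
    }
    # candidates: identified 13C monoisotopic peaks (mirrored-chain anchors)
    # plus unattached singleton peaks -- at label purity 1.0 a fully labeled
    # peak has no lighter isotopologues and hence no mirrored chain
    fwd_mono_ids = {ch.monoisotopic_peak for ch in chains if not ch.mirrored}
    singleton = [
        p.id
        for p in peaks
        if p.id not in fwd_member
        and p.id not in fwd_mono_ids
        and p.id not in mir_member
        and p.id not in mir_mono
        and p.id not in annotated
    ]
    c13_candidates = [
        by_id[pid]
        for pid in sorted(set(mir_mono) | set(singleton))
        if pid in by_id and pid not in annotated
    ]
    pairs: list[LabelPair] = []
    seen_pairs: set[tuple[str, str, int]] = set()
    for spec in spectra:
        # a 13C peak may serve several spectra (multi-membership is legal
        # until claim_peaks) but only one 12C partner within each spectrum
        used_c13: set[str] = set()
        range_cache: dict[str, set[int]] = {}
        for ann in list(spec.annotations):
            if ann.role not in ("seed_adduct", "adduct", "fragment"):
                continue
            sp = ann.species
            if sp is None or sp.multiplicity != 1:
                continue
            p = by_id[ann.peak]
            z = abs(sp.charge)
            if ann.ion_label not in range_cache:
                range_cache[ann.ion_label] = _allowed_carbons(ann, spec.M, cfg)
            allowed = range_cache[ann.ion_label]
            best: tuple[float, Peak, int] | None = None
            for q in c13_candidates:
                if q.id in used_c13 or abs(q.rt - p.rt) > cfg.eps_rt:
                    continue
                if q.mz <= p.mz:
                    continue
                n = round((q.mz - p.mz) * z / C13_DELTA)
                if n < 1 or n not in allowed:
                    continue
                # check against the spectrum's (averaged, less noisy) M via
                # the consistency requirement |mz - ion_mz(M, sp, n)| <= eps
                err = abs(q.mz - ion_mz(spec.M, sp, n))
                if err <= cfg.eps_mz and (best is None or err < best[0]):
                    best = (err, q, n)
            if best is None:
                continue
            _, q, n = best
            used_c13.add(q.id)
            if (p.id, q.id, n) not in seen_pairs:
                seen_pairs.add((p.id, q.id, n))
                pairs.append(LabelPair(c12_peak=p.id, c13_peak=q.id, n=n))
            spec.annotations.append(
                PeakAnnotation(
                    peak=q.id,
                    ion_label=_shifted_label(ann.ion_label, n),
                    role="c13_monoisotopic",
                    species=sp,
                    shift=n,
                )
            )
            chain = mir_mono.get(q.id)
            if chain:
                for k, mid in enumerate(chain.members[1:], start=1):
                    spec.annotations.append(
                        PeakAnnotation(
                            peak=mid,
                            ion_label=f"{_shifted_label(ann.ion_label, n)} (-{k})",
                            role="c13_isotope",
                            species=sp,
                            shift=n - k,
                        )
                    )
    return pairs


# ----------------------------------------------------------------------
# step 5: homoadducts
# ----------------------------------------------------------------------

def detect_homoadducts(
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    label_pairs: Sequence[LabelPair],
    cfg: SDConfig,
    chains: Sequence[IsotopeChain] = (),
) -> None:
    """Annotate unassigned peaks matching multimer species of each known M,
    including the mixed-label shift of the primary pair (``[2M+n+H]+``)."""
    by_id = {p.id: p for p in peaks}
    fwd_mono, _, _, _ = _chain_index(chains)
    assigned = {a.peak for s in spectra for a in s.annotations}
    multimers = [
        s for s in cfg.ion_list if s.multiplicity >= 2 and s.mode == cfg.mode
    ]
    pair_by_c12 = {lp.c12_peak: lp for lp in label_pairs}
    free = sorted(
        (p for p in peaks if p.id not in assigned), key=lambda p: (p.mz, p.id)
    )
    for spec in sorted(spectra, key=lambda s: (s.M, s.rt)):
        prim = spec.primary()
        shifts = [0]
        if prim is not None and prim.peak in pair_by_c12:
            shifts.append(pair_by_c12[prim.peak].n)
        for sp in multimers:
            for shift in shifts:
                try:
                    expect = ion_mz(spec.M, sp, shift)
                except ValueError:
                    continue
                best = None
                for p in free:
                    if p.id in assigned or abs(p.rt - spec.rt) > cfg.eps_rt:
                        continue
                    err = abs(p.mz - expect)
                    if err <= cfg.eps_mz and (best is None or err < best[0]):
                        best = (err, p)
                if best is None:
                    continue
                p = best[1]
                assigned.add(p.id)
                label = sp.label if shift == 0 else _shifted_label(sp.label, shift)
                spec.annotations.append(
                    PeakAnnotation(
                        peak=p.id,
                        ion_label=label,
                        role="homoadduct",
                        species=sp,
                        shift=shift,
                    )
                )
                chain = fwd_mono.get(p.id)
                if chain:
                    for k, mid in enumerate(chain.members[1:], start=1):
                        if mid in assigned:
                            continue
                        assigned.add(mid)
                        spec.annotations.append(
                            PeakAnnotation(
                                peak=mid,
                                ion_label=f"{label} (+{k})",
                                role="isotope",
                                species=sp,
                                shift=shift + k,
                            )
                        )


# ----------------------------------------------------------------------
# step 6: uncommon neutral losses
# ----------------------------------------------------------------------

def annotate_uncommon_losses(
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    chains: Sequence[IsotopeChain],
    label_pairs: list[LabelPair],
    cfg: SDConfig,
) -> None:
    """For spectra whose pseudo-molecular ion has a 13C partner (carbon
    count n_p known), explain unassigned 12C/13C peak pairs at lower m/z as
    in-source fragments: decompose the primary mass (fixed n_p carbons), the
    fragment mass (n_f) and the loss mass (n_p - n_f) and search for
    triplets with ``s_p = s_f + s_l``.  A unique triplet sets the loss
    formula; multiple triplets flag the annotation as ambiguous."""
    if not cfg.labeled:
        return
    by_id = {p.id: p for p in peaks}
    _, _, mir_mono, mir_member = _chain_index(chains)
    pair_by_c12 = {lp.c12_peak: lp for lp in label_pairs}

    def decomp(mass: float, carbons: int) -> list[Formula]:
        if mass <= 0:
            return []
        return decompose(
            DecompositionQuery(
                target_mass=mass,
                tolerance=cfg.decomp_tolerance,
                bounds=cfg.bounds,
                fixed_carbon=carbons,
                filters=CHEMISTRY_FILTERS,
            )
        )

    for spec in sorted(spectra, key=lambda s: (s.M, s.rt)):
        prim = spec.primary()
        if prim is None or prim.ion_label not in ("[M+H]+", "[M-H]-"):
            continue
        lp = pair_by_c12.get(prim.peak)
        if lp is None:
            continue
        n_p = lp.n
        sign = 1 if prim.ion_label == "[M+H]+" else -1
        p = by_id[prim.peak]
        assigned = {a.peak for s in spectra for a in s.annotations}
        s_p_set = decomp(spec.M, n_p)
        if not s_p_set:
            continue
        free12 = [
            q
            for q in peaks
            if q.id not in assigned
            and q.id not in mir_mono
            and q.id not in mir_member
            and q.mz < p.mz
            and abs(q.rt - p.rt) <= cfg.eps_rt
        ]
        fwd_mono_ids = {ch.monoisotopic_peak for ch in chains if not ch.mirrored}
        fwd_member_ids = {
            m for ch in chains if not ch.mirrored for m in ch.members[1:]
        }
        free12 = [q for q in free12 if q.id not in fwd_member_ids]
        singleton_ids = {
            q.id
            for q in peaks
            if q.id not in assigned
            and q.id not in fwd_mono_ids
            and q.id not in fwd_member_ids
            and q.id not in mir_mono
            and q.id not in mir_member
        }
        c13_cands = [
            by_id[pid]
            for pid in sorted(set(mir_mono) | singleton_ids)
            if pid in by_id and pid not in assigned
        ]
        for a in sorted(free12, key=lambda q: (q.mz, q.id)):
            best = None
            for b in c13_cands:
                if b.mz <= a.mz or abs(b.rt - a.rt) > cfg.eps_rt:
                    continue
                n_f = round((b.mz - a.mz) / C13_DELTA)
                if not (1 <= n_f < n_p):
                    continue
                err = abs(b.mz - (a.mz + n_f * C13_DELTA))
                if err <= cfg.eps_mz and (best is None or err < best[0]):
                    best = (err, b, n_f)
            if best is None:
                continue
            _, b, n_f = best
            frag_neutral = a.mz - sign * PROTON_MASS
            loss_mass = abs(p.mz - a.mz)
            s_f_set = decomp(frag_neutral, n_f)
            s_l_set = decomp(loss_mass, n_p - n_f)
            triplets = [
                (sp_, sf_, sl_)
                for sp_ in s_p_set
                for sf_ in s_f_set
                for sl_ in s_l_set
                if sf_ + sl_ == sp_
            ]
            if not triplets:
                continue
            unique = len(set(triplets)) == 1
            # order triplets by combined mass error for a deterministic pick
            triplets.sort(
                key=lambda t: (
                    abs(t[1].mass - frag_neutral) + abs(t[2].mass - loss_mass),
                    t[2].hill(),
                )
            )
            loss = triplets[0][2]
            head = prim.ion_label[:-2]  # "[M+H" or "[M-H"
            tail = prim.ion_label[-2:]
            label = f"{head}-{loss.hill()}{tail}"
            spec.annotations.append(
                PeakAnnotation(
                    peak=a.id,
                    ion_label=label,
                    role="fragment",
                    loss_formula=loss if unique else None,
                    ambiguous=not unique,
                )
            )
            spec.annotations.append(
                PeakAnnotation(
                    peak=b.id,
                    ion_label=_shifted_label(label, n_f),
                    role="c13_monoisotopic",
                    shift=n_f,
                    ambiguous=not unique,
                )
            )
            label_pairs.append(LabelPair(c12_peak=a.id, c13_peak=b.id, n=n_f))
            c13_cands = [c for c in c13_cands if c.id != b.id]


# ----------------------------------------------------------------------
# step 7: correlation pruning
# ----------------------------------------------------------------------

def eic_correlation(a: Peak, b: Peak) -> float:
    """Pearson correlation of two peaks' EIC intensities over the
    overlapping RT range, resampled onto a common grid."""
    if a.eic is None or b.eic is None or a.eic.empty or b.eic.empty:
        raise CorrelationUnavailable(
            f"missing EIC trace for {a.id if a.eic is None or a.eic.empty else b.id}"
        )
    lo = max(a.eic.rt[0], b.eic.rt[0])
    hi = min(a.eic.rt[-1], b.eic.rt[-1])
    if hi <= lo:
        raise CorrelationUnavailable(f"no RT overlap between {a.id} and {b.id}")
    mask = (a.eic.rt >= lo) & (a.eic.rt <= hi)
    grid = a.eic.rt[mask]
    if grid.size < 3:
        raise CorrelationUnavailable("overlap region has fewer than 3 points")
    ya = a.eic.intensity[mask]
    yb = np.interp(grid, b.eic.rt, b.eic.intensity)
    if np.allclose(ya, ya[0]) or np.allclose(yb, yb[0]):
        raise CorrelationUnavailable("constant trace in overlap region")
    r = float(np.corrcoef(ya, yb)[0, 1])
    return max(-1.0, min(1.0, r))


def prune_by_correlation(
    spectra: Sequence[PseudoSpectrum],
    peaks: Sequence[Peak],
    cfg: SDConfig,
) -> None:
    """Drop members whose correlation to the primary peak falls below the
    threshold.  The primary is always retained; peaks without computable
    correlation are kept but flagged unverified."""
    by_id = {p.id: p for p in peaks}
    if not any(p.eic is not None and not p.eic.empty for p in peaks):
        logger.warning("no EIC traces available; correlation pruning skipped")
        return
    for spec in spectra:
        prim = spec.primary()
        if prim is None:
            continue
        pp = by_id[prim.peak]
        drop: set[str] = set()
        for pid in spec.member_ids():
            if pid == prim.peak:
                continue
            try:
                r = eic_correlation(pp, by_id[pid])
            except CorrelationUnavailable:
                for a in spec.annotations_for(pid):
                    a.unverified = True
                continue
            if r < cfg.correlation_threshold:
                drop.add(pid)
        if drop:
            spec.annotations = [a for a in spec.annotations if a.peak not in drop]


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

def deconvolve(peaks: Sequence[Peak], cfg: SDConfig | None = None) -> DeconvolutionResult:
    """Run steps 2-7 on one chromatogram's peaks.  Deterministic for a
    fixed input and configuration."""
    cfg = cfg or SDConfig()
    peaks = list(peaks)
    if not peaks:
        return DeconvolutionResult([], [], [], [])
    samples = {p.sample for p in peaks}
    if len(samples) > 1:
        raise ValueError(f"peaks from multiple chromatograms: {sorted(samples)}")
    chains = detect_isotope_chains(peaks, cfg)
    spectra = assemble_pseudo_spectra(peaks, chains, cfg)
    pairs = associate_label_pairs(spectra, peaks, chains, cfg)
    detect_homoadducts(spectra, peaks, pairs, cfg, chains)
    annotate_uncommon_losses(spectra, peaks, chains, pairs, cfg)
    prune_by_correlation(spectra, peaks, cfg)
    spectra = [s for s in spectra if any(a.role == "seed_adduct" for a in s.annotations)]
    member_ids = {a.peak for s in spectra for a in s.annotations}
    orphans = [p.id for p in sorted(peaks, key=lambda q: (q.mz, q.id)) if p.id not in member_ids]
    spectra.sort(key=lambda s: (s.M, s.rt))
    return DeconvolutionResult(spectra, chains, pairs, orphans)


# ----------------------------------------------------------------------
# curation operations
# ----------------------------------------------------------------------

def claim_peaks(
    target: PseudoSpectrum, peak_ids: Iterable[str], spectra: Sequence[PseudoSpectrum]
) -> None:
    """Remove the claimed peaks from every pseudo spectrum except ``target``
    so that each appears in exactly one spectrum afterwards."""
    ids = list(peak_ids)
    members = set(target.member_ids())
    foreign = [pid for pid in ids if pid not in members]
    if foreign:
        raise ValueError(f"peaks not in target spectrum {target.id}: {foreign}")
    for spec in spectra:
        if spec is target:
            continue
        spec.annotations = [a for a in spec.annotations if a.peak not in ids]


def list_orphans(
    peaks: Sequence[Peak],
    spectra: Sequence[PseudoSpectrum],
    rt_window: tuple[float, float] | None = None,
    min_intensity: float = 0.0,
) -> list[str]:
    """Peaks in no pseudo spectrum, filtered by RT window and intensity."""
    members = {a.peak for s in spectra for a in s.annotations}
    lo, hi = rt_window if rt_window is not None else (-math.inf, math.inf)
    return [
        p.id
        for p in sorted(peaks, key=lambda q: (q.mz, q.id))
        if p.id not in members and lo <= p.rt <= hi and p.intensity >= min_intensity
    ]


def find_correlating_peaks(
    spectrum: PseudoSpectrum,
    peaks: Sequence[Peak],
    threshold: float = 0.75,
    spectra: Sequence[PseudoSpectrum] | None = None,
    eps_rt: float = 5.0,
) -> list[tuple[str, float]]:
    """Orphan peaks near the spectrum's RT whose EIC correlation to the
    primary peak reaches the threshold, ranked by correlation."""
    by_id = {p.id: p for p in peaks}
    prim = spectrum.primary()
    if prim is None:
        return []
    pp = by_id[prim.peak]
    pool = spectra if spectra is not None else [spectrum]
    orphan_ids = list_orphans(peaks, pool)
    out: list[tuple[str, float]] = []
    for pid in orphan_ids:
        q = by_id[pid]
        if abs(q.rt - spectrum.rt) > eps_rt:
            continue
        try:
            r = eic_correlation(pp, q)
        except CorrelationUnavailable:
            continue
        if r >= threshold:
            out.append((pid, r))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
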