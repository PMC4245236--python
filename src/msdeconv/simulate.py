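"""Synthetic peak tables with full ground truth.

Generates coeluting compounds emitting correlated adduct / fragment /
isotopologue peaks, with natural and "mirrored" 13C isotope patterns
(uniformly labeled internal standard), configurable m/z and RT noise, and
contaminant peaks.  Every non-contaminant peak is linked to its origin in a
ground-truth map so pipeline recovery can be scored exactly.

The isotope model is carbon-only (binomial on the carbon count); it is a
test harness, not a general isotope-pattern simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chem import (
    C13_DELTA,
    Formula,
    IonSpeciesDef,
    PROTON_MASS,
    default_ion_list,
    formula_mass,
    ion_mz,
    parse_formula,
)
from .pipeline import EIC, DeconvolutionResult, Peak, SDConfig

__all__ = [
    "P_C13_NATURAL",
    "GroundTruthCompound",
    "NoiseModel",
    "TruthRecord",
    "natural_isotope_pattern",
    "mirrored_pattern",
    "simulate_peak_table",
    "simulate_eics",
    "preset_scenarios",
    "build_preset",
    "evaluate_recovery",
]

#: Natural abundance of 13C.
P_C13_NATURAL = 0.0107


def natural_isotope_pattern(f: Formula | str, k: int) -> list[float]:
    """Relative intensities of M, M+1, ... M+k-1 under a carbon-binomial
    model, normalized so the monoisotopic peak is 1."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(f, str):
        f = parse_formula(f)
    n = f.get("C")
    r = P_C13_NATURAL / (1.0 - P_C13_NATURAL)
    out = []
    for i in range(k):
        out.append(math.comb(n, i) * r**i if i <= n else 0.0)
    return out


def mirrored_pattern(f: Formula | str, k: int, purity: float) -> list[float]:
    """Relative intensities of M_full, M_full-1, ... for an incompletely
    13C-labeled compound (label purity in (0, 1]); mirror image of the
    natural pattern, descending toward lower mass."""
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(f, str):
        f = parse_formula(f)
    n = f.get("C")
    if purity == 1.0 or n == 0:
        return [1.0] + [0.0] * (k - 1)
    r = (1.0 - purity) / purity
    return [math.comb(n, i) * r**i if i <= n else 0.0 for i in range(k)]


@dataclass
class GroundTruthCompound:
    name: str
    formula: Formula
    rt: float
    rt_sigma: float = 3.0
    base_abundance: float = 1e6
    label_abundance: float = 0.0
    species: list[tuple[IonSpeciesDef, float]] = field(default_factory=list)
    extra_fragments: list[tuple[Formula, float]] = field(default_factory=list)
    label_purity: float = 0.99

    def __post_init__(self):
        if not (0.0 < self.label_purity <= 1.0):
            raise ValueError("label_purity must be in (0, 1]")
        for _, y in self.species + [(None, y) for _, y in self.extra_fragments]:
            if y <= 0:
                raise ValueError("species yields must be positive")


@dataclass
class NoiseModel:
    mz_sd: float = 0.0
    rt_jitter_sd: float = 0.0
    intensity_cv: float = 0.0
    n_contaminant_peaks: int = 0
    seed: int = 0

    def __post_init__(self):
        for attr in ("mz_sd", "rt_jitter_sd", "intensity_cv", "n_contaminant_peaks"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Origin of one emitted peak."""

    compound: str
    species_label: str  # expected ion label in the deconvolution result
    isotope_index: int  # 0 = monoisotopic, +k natural, -k mirrored
    labeled: bool
    shift: int  # 13C label shift of the monoisotopic peak (0 for 12C)
    role: str  # expected annotation role of the monoisotopic peak
    expect_auto: bool  # recoverable by the automatic pipeline


def _fragment_species(loss: Formula) -> IonSpeciesDef:
    return IonSpeciesDef(
        label=f"[M+H-{loss.hill()}]+",
        delta_mass=PROTON_MASS - loss.mass,
        charge=1,
        multiplicity=1,
        is_seed=False,
        mode="positive",
        loss_formula=loss,
    )


def _shifted(label: str, n: int) -> str:
    for head in ("[2M", "[M"):
        if label.startswith(head):
            return f"{head}+{n}" + label[len(head):]
    return f"{label}+{n}"


def simulate_peak_table(
    compounds: Sequence[GroundTruthCompound],
    noise: NoiseModel | None = None,
    cfg: SDConfig | None = None,
    n_isotopologues: int = 3,
    uncommon_losses_auto: bool = True,
) -> tuple[list[Peak], dict[str, TruthRecord]]:
    """Emit one synthetic chromatogram peak table plus its ground truth.

    For each compound and species: a 12C monoisotopic peak, natural
    isotopologues, and -- when ``label_abundance > 0`` -- the fully labeled
    counterpart with a mirrored pattern.  Homoadducts additionally get the
    mixed-label peak (one labeled moiety).  Deterministic per seed.
    """
    if not compounds:
        raise ValueError("at least one compound required")
    noise = noise or NoiseModel()
    cfg = cfg or SDConfig()
    rng = np.random.default_rng(noise.seed)
    peaks: list[Peak] = []
    truth: dict[str, TruthRecord] = {}
    counter = [0]

    def emit(mz, rt_c, sigma, inten, rec: TruthRecord | None):
        counter[0] += 1
        pid = f"p{counter[0]:04d}"
        mz_obs = mz + rng.normal(0.0, noise.mz_sd) if noise.mz_sd else mz
        rt_obs = rt_c + (rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else 0.0)
        if noise.intensity_cv:
            inten = max(inten * (1.0 + rng.normal(0.0, noise.intensity_cv)), 1.0)
        area = inten * sigma * math.sqrt(2.0 * math.pi)
        peaks.append(
            Peak(
                id=pid,
                mz=mz_obs,
                rt=rt_obs,
                rt_min=rt_obs - 2 * sigma,
                rt_max=rt_obs + 2 * sigma,
                maxo=inten,
                into=area,
                intb=area,
            )
        )
        if rec is not None:
            truth[pid] = rec
        return pid

    for comp in compounds:
        M = comp.formula.mass
        n_c = comp.formula.get("C")
        all_species: list[tuple[IonSpeciesDef, float, bool]] = [
            (sp, y, True) for sp, y in comp.species
        ]
        all_species += [
            (_fragment_species(loss), y, False) for loss, y in comp.extra_fragments
        ]
        for sp, y, predefined in all_species:
            z = abs(sp.charge)
            loss_c = sp.loss_formula.get("C") if sp.loss_formula is not None else 0
            ion_c = n_c * sp.multiplicity - loss_c
            ion_cf = Formula({"C": ion_c}) if ion_c > 0 else Formula()
            base_int = comp.base_abundance * y
            label_for_12c = sp.label if predefined else sp.label
            role = (
                "homoadduct"
                if sp.multiplicity > 1
                else "seed_adduct"
                if sp.is_seed
                else "fragment"
                if sp.loss_formula is not None
                else "adduct"
            )
            # 12C monoisotopic + natural isotopologues
            pattern = natural_isotope_pattern(ion_cf, n_isotopologues)
            mz0 = ion_mz(M, sp, 0)
            emit(
                mz0,
                comp.rt,
                comp.rt_sigma,
                base_int,
                TruthRecord(
                    comp.name, label_for_12c, 0, False, 0, role,
                    expect_auto=predefined or uncommon_losses_auto,
                ),
            )
            for i in range(1, n_isotopologues):
                if pattern[i] <= 0:
                    continue
                emit(
                    mz0 + i * C13_DELTA / z,
                    comp.rt,
                    comp.rt_sigma,
                    base_int * pattern[i],
                    TruthRecord(
                        comp.name, label_for_12c, i, False, 0, "isotope",
                        expect_auto=predefined,
                    ),
                )
            # fully labeled counterpart with mirrored pattern
            if comp.label_abundance > 0 and ion_c > 0 and sp.multiplicity == 1:
                lab_int = comp.label_abundance * y
                mzl = ion_mz(M, sp, ion_c)
                mir = mirrored_pattern(ion_cf, n_isotopologues, comp.label_purity)
                emit(
                    mzl,
                    comp.rt,
                    comp.rt_sigma,
                    lab_int,
                    TruthRecord(
                        comp.name, _shifted(sp.label, ion_c), 0, True, ion_c,
                        "c13_monoisotopic",
                        expect_auto=predefined or uncommon_losses_auto,
                    ),
                )
                for i in range(1, n_isotopologues):
                    if mir[i] <= 0:
                        continue
                    emit(
                        mzl - i * C13_DELTA / z,
                        comp.rt,
                        comp.rt_sigma,
                        lab_int * mir[i],
                        TruthRecord(
                            comp.name, _shifted(sp.label, ion_c), -i, True, ion_c,
                            "c13_isotope", expect_auto=predefined,
                        ),
                    )
            # mixed-label homoadduct: one unlabeled + one labeled moiety
            if comp.label_abundance > 0 and sp.multiplicity == 2:
                mixed_int = comp.label_abundance * y
                emit(
                    ion_mz(M, sp, n_c),
                    comp.rt,
                    comp.rt_sigma,
                    mixed_int,
                    TruthRecord(
                        comp.name, _shifted(sp.label, n_c), 0, True, n_c,
                        "homoadduct", expect_auto=True,
                    ),
                )

    if noise.n_contaminant_peaks:
        rts = [c.rt for c in compounds]
        lo, hi = min(rts) - 60.0, max(rts) + 60.0
        for _ in range(noise.n_contaminant_peaks):
            emit(
                float(rng.uniform(80.0, 600.0)),
                float(rng.uniform(lo, hi)),
                2.0,
                float(rng.uniform(1e3, 1e4)),
                None,
            )
    return peaks, truth


def simulate_eics(
    peaks: Sequence[Peak],
    truth: dict[str, TruthRecord],
    compounds: Sequence[GroundTruthCompound],
    dt: float = 0.5,
    rt_pad: float = 12.0,
) -> None:
    """Attach Gaussian EIC traces in place.  All peaks of one compound share
    the compound's RT profile (pairwise correlation ~1); contaminants get
    independent profiles centered on their own RT."""
    if dt <= 0:
        raise ValueError("grid step dt must be positive")
    by_name = {c.name: c for c in compounds}
    for p in peaks:
        rec = truth.get(p.id)
        if rec is not None and rec.compound in by_name:
            comp = by_name[rec.compound]
            center, sigma = comp.rt, comp.rt_sigma
        else:
            center, sigma = p.rt, max((p.rt_max - p.rt_min) / 4.0, 1.0)
        grid = np.arange(center - rt_pad, center + rt_pad + dt / 2, dt)
        trace = p.maxo * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        p.eic = EIC(rt=grid, intensity=trace)


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

def _species(label: str, ion_list: Sequence[IonSpeciesDef]) -> IonSpeciesDef:
    for sp in ion_list:
        if sp.label == label:
            return sp
    raise KeyError(label)


def preset_scenarios() -> dict[str, str]:
    """Names and short descriptions of the shipped scenarios."""
    return {
        "glutamate": "single C5H9NO4 compound, six 12C ion species incl. "
        "[2M+H]+ and the mixed-label [2M+5+H]+",
        "glu_met_dipeptide": "C10H18N2O5S dipeptide with a C5H11NO2S "
        "residue fragment, exercising uncommon-loss triplets",
        "coeluting_pair": "glutamate with cascading losses whose fragments "
        "also assemble into a second spectrum (claim-peaks scenario)",
        "unlabeled_standard_missing": "glutamate without the labeled "
        "internal standard (undefined isotopomer ratios)",
    }


def build_preset(
    name: str,
    label_abundance: float = 5e5,
    emit_double_labeled_homoadduct: bool = False,
) -> tuple[list[GroundTruthCompound], SDConfig]:
    """Construct the compound list and a matching pipeline config for one
    named scenario."""
    ions = default_ion_list("positive")
    cfg = SDConfig(ion_list=ions)
    glu = parse_formula("C5H9NO4")
    if name == "glutamate" or name == "unlabeled_standard_missing":
        lab = 0.0 if name == "unlabeled_standard_missing" else label_abundance
        comp = GroundTruthCompound(
            name="glutamate",
            formula=glu,
            rt=287.92,
            species=[
                (_species("[M+H]+", ions), 1.0),
                (_species("[M+Na]+", ions), 0.35),
                (_species("[M+K]+", ions), 0.18),
                (_species("[M+H-H2O]+", ions), 0.5),
                (_species("[M+H-HCOOH]+", ions), 0.4),
                (_species("[2M+H]+", ions), 0.2),
            ],
            label_abundance=lab,
        )
        return [comp], cfg
    if name == "glu_met_dipeptide":
        comp = GroundTruthCompound(
            name="glutamyl-methionine",
            formula=parse_formula("C10H18N2O5S"),
            rt=402.5,
            species=[
                (_species("[M+H]+", ions), 1.0),
                (_species("[M+Na]+", ions), 0.3),
                (_species("[M+H-H2O]+", ions), 0.25),
            ],
            extra_fragments=[(parse_formula("C5H7NO3"), 0.5)],
            label_abundance=label_abundance,
        )
        return [comp], cfg
    if name == "coeluting_pair":
        # cascading small losses: the water/formic-acid fragments double as
        # a plausible second compound (M = 129.04), exercising claim_peaks
        combo = _fragment_species(parse_formula("CH2O3"))  # HCOOH + H2O
        cfg.ion_list = ions + [combo]
        comp = GroundTruthCompound(
            name="glutamate",
            formula=glu,
            rt=287.92,
            species=[
                (_species("[M+H]+", ions), 1.0),
                (_species("[M+Na]+", ions), 0.35),
                (_species("[M+H-H2O]+", ions), 0.5),
                (_species("[M+H-HCOOH]+", ions), 0.4),
                (combo, 0.3),
            ],
            label_abundance=label_abundance,
        )
        return [comp], cfg
    raise ValueError(f"unknown preset {name!r}")


# ----------------------------------------------------------------------
# recovery scoring
# ----------------------------------------------------------------------

def evaluate_recovery(
    result: DeconvolutionResult, truth: dict[str, TruthRecord]
) -> dict[str, tuple[int, int]]:
    """Compare a deconvolution result against the ground-truth map.

    Returns per-category ``(recovered, expected)`` counts for 12C ion
    labels, labeled (13C) monoisotopic labels, homoadduct labels and label
    pairs with the correct carbon count n.  Only records flagged
    ``expect_auto`` count toward the denominators.
    """
    labels_by_peak: dict[str, set[str]] = {}
    for spec in result.spectra:
        for a in spec.annotations:
            labels_by_peak.setdefault(a.peak, set()).add(a.ion_label)
    pair_n = {(lp.c12_peak, lp.n) for lp in result.label_pairs}
    pair_c13 = {(lp.c13_peak, lp.n) for lp in result.label_pairs}

    cats = {
        "ion_labels": [0, 0],
        "c13_labels": [0, 0],
        "homoadducts": [0, 0],
        "label_pairs": [0, 0],
    }
    for pid, rec in truth.items():
        if not rec.expect_auto or rec.isotope_index != 0:
            continue
        got = labels_by_peak.get(pid, set())
        hit = rec.species_label in got
        if rec.role == "homoadduct":
            cats["homoadducts"][1] += 1
            cats["homoadducts"][0] += int(hit)
        elif rec.labeled:
            cats["c13_labels"][1] += 1
            cats["c13_labels"][0] += int(hit)
            cats["label_pairs"][1] += 1
            cats["label_pairs"][0] += int((pid, rec.shift) in pair_c13)
        else:
            cats["ion_labels"][1] += 1
            cats["ion_labels"][0] += int(hit)
    return {k: (v[0], v[1]) for k, v in cats.items()}
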