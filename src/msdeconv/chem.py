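"""Element masses, sum-formula arithmetic and ion-species m/z conversions.

Everything downstream (decomposition, pseudo-spectrum assembly, the
synthetic generator) builds on the primitives defined here: :class:`Formula`,
:class:`IonSpeciesDef` and the ``ion_mz`` / ``neutral_mass_from_mz`` pair.

Conventions
-----------
* Monoisotopic element masses from the standard table (CODATA-derived).
* Ion ``delta_mass`` values are computed from element masses with explicit
  electron bookkeeping (a proton is H minus an electron, 1.007276 Da).
* The 13C-12C mass increment is fixed at 1.003355 Da.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_DELTA",
    "Formula",
    "IonSpeciesDef",
    "parse_formula",
    "formula_mass",
    "ion_mz",
    "neutral_mass_from_mz",
    "default_ion_list",
    "load_ion_list",
    "save_ion_list",
]

#: Monoisotopic masses in Da of the elements this package knows about.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "Cl": 34.96885271,
}

PROTON_MASS: float = 1.007276466879
ELECTRON_MASS: float = 0.000548579909
#: Mass increment of one 13C over 12C, fixed by convention.
C13_DELTA: float = 1.003355

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """Immutable element -> count mapping with mass arithmetic.

    Counts are non-negative integers; zero counts are dropped.  Addition and
    subtraction are elementwise; subtraction raises if any count would go
    negative (an impossible neutral loss).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in MONOISOTOPIC_MASS:
                    raise ValueError(f"unknown element symbol: {el!r}")
                n = int(n)
                if n < 0:
                    raise ValueError(f"negative count for element {el}: {n}")
                if n:
                    merged[el] = merged.get(el, 0) + n
        self._counts = merged
        self._hash: int | None = None

    # -- Mapping protocol ------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, el: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(el, default)

    # -- identity --------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(tuple(sorted(self._counts.items())))
        return self._hash

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        out = dict(self._counts)
        for el, n in other.items():
            res = out.get(el, 0) - n
            if res < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({self.hill()} - {other.hill()})"
                )
            out[el] = res
        return Formula(out)

    def contains(self, sub: "Formula") -> bool:
        """Elementwise ``self >= sub``."""
        return all(self.get(el) >= n for el, n in sub.items())

    @property
    def mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self._counts.items())

    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then alphabetical."""
        parts = []
        for el in ("C", "H"):
            n = self.get(el)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(self._counts):
            if el in ("C", "H"):
                continue
            n = self._counts[el]
            parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return parse_formula(text)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style element-count string, e.g. ``"C5H9NO4"``.

    Raises ``ValueError`` naming the offending position for malformed input
    or unknown element symbols.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(
                f"unknown element symbol {el!r} in {text!r} at position {pos}"
            )
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def formula_mass(f: Formula | str) -> float:
    """Monoisotopic mass in Da of a formula (or formula string)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return f.mass


@dataclass(frozen=True)
class IonSpeciesDef:
    """Definition of one ion species such as ``[M+H]+`` or ``[2M+Na]+``.

    ``delta_mass`` is the signed mass added to ``multiplicity * M`` before
    dividing by ``|charge|``.  ``loss_formula`` is set for predefined
    neutral-loss fragments (e.g. H2O for ``[M+H-H2O]+``) so that carbon
    bookkeeping of labeled counterparts stays correct.
    """

    label: str
    delta_mass: float
    charge: int = 1
    multiplicity: int = 1
    is_seed: bool = False
    mode: str = "positive"
    loss_formula: Formula | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("ion charge must be non-zero")
        if abs(self.charge) not in (1, 2):
            raise ValueError("|charge| must be 1 or 2")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.is_seed and self.multiplicity != 1:
            raise ValueError("seed species must have multiplicity 1")
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown mode {self.mode!r}")


def ion_mz(M: float, ion: IonSpeciesDef, label_shift: int = 0) -> float:
    """m/z of ion species ``ion`` for neutral mass ``M``.

    ``label_shift`` adds ``n`` 13C mass increments (labeled isotopologues).
    """
    if M <= 0:
        raise ValueError(f"neutral mass must be positive, got {M}")
    if label_shift < 0:
        raise ValueError("label_shift must be >= 0")
    return (ion.multiplicity * M + ion.delta_mass + label_shift * C13_DELTA) / abs(
        ion.charge
    )


def neutral_mass_from_mz(mz: float, ion: IonSpeciesDef) -> float:
    """Neutral mass implied by observing ``ion`` at ``mz`` (label shift 0)."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    M = (mz * abs(ion.charge) - ion.delta_mass) / ion.multiplicity
    if M <= 0:
        raise ValueError(
            f"non-positive neutral mass {M:.4f} for {ion.label} at m/z {mz}"
        )
    return M


def _delta(gain: str | None = None, lose: str | None = None, charge: int = 1) -> float:
    """delta_mass from gained/lost atoms with electron bookkeeping."""
    d = -charge * ELECTRON_MASS
    if gain:
        d += formula_mass(gain)
    if lose:
        d -= formula_mass(lose)
    return d


def _pos(label, *, gain=None, lose=None, charge=1, mult=1, seed=False):
    return IonSpeciesDef(
        label=label,
        delta_mass=_delta(gain, lose, charge),
        charge=charge,
        multiplicity=mult,
        is_seed=seed,
        mode="positive",
        loss_formula=parse_formula(lose) if lose else None,
    )


def _neg(label, *, gain=None, lose=None, mult=1, seed=False):
    return IonSpeciesDef(
        label=label,
        delta_mass=_delta(gain, lose, -1),
        charge=-1,
        multiplicity=mult,
        is_seed=seed,
        mode="negative",
        loss_formula=parse_formula(lose) if lose else None,
    )


def default_ion_list(mode: str = "positive") -> list[IonSpeciesDef]:
    """Shipped default adduct/neutral-loss species for one acquisition mode.

    Fully user-editable via config files (see :func:`load_ion_list`).
    """
    if mode == "positive":
        return [
            _pos("[M+H]+", gain="H", seed=True),
            _pos("[M+Na]+", gain="Na", seed=True),
            _pos("[M+K]+", gain="K", seed=True),
            _pos("[M+NH4]+", gain="NH4"),
            _pos("[M+2H]2+", gain="H2", charge=2),
            _pos("[M+H-H2O]+", gain="H", lose="H2O"),
            _pos("[M+H-NH3]+", gain="H", lose="NH3"),
            _pos("[M+H-HCOOH]+", gain="H", lose="CH2O2"),
            _pos("[M+H-CO]+", gain="H", lose="CO"),
            _pos("[M+H-CO2]+", gain="H", lose="CO2"),
            _pos("[2M+H]+", gain="H", mult=2),
            _pos("[2M+Na]+", gain="Na", mult=2),
        ]
    if mode == "negative":
        return [
            _neg("[M-H]-", lose="H", seed=True),
            _neg("[M+Cl]-", gain="Cl"),
            _neg("[M-H-H2O]-", lose="H3O"),
            _neg("[2M-H]-", lose="H", mult=2),
        ]
    raise ValueError(f"unknown mode {mode!r}")


# -- ion-list config I/O (TSV or JSON) ----------------------------------

_ION_FIELDS = ("label", "delta_mass", "charge", "multiplicity", "is_seed", "mode")


def _ion_to_dict(ion: IonSpeciesDef) -> dict:
    d = {k: getattr(ion, k) for k in _ION_FIELDS}
    if ion.loss_formula is not None:
        d["loss_formula"] = ion.loss_formula.hill()
    return d


def _ion_from_dict(d: dict) -> IonSpeciesDef:
    loss = d.get("loss_formula") or None
    return IonSpeciesDef(
        label=str(d["label"]),
        delta_mass=float(d["delta_mass"]),
        charge=int(d["charge"]),
        multiplicity=int(d.get("multiplicity", 1)),
        is_seed=_as_bool(d.get("is_seed", False)),
        mode=str(d.get("mode", "positive")),
        loss_formula=parse_formula(loss) if loss else None,
    )


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def load_ion_list(path: str | Path) -> list[IonSpeciesDef]:
    """Read an adduct/loss list from JSON (list of objects) or TSV."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        return [_ion_from_dict(d) for d in json.loads(text)]
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        out.append(_ion_from_dict(dict(zip(header, ln.split("\t")))))
    return out


def save_ion_list(ions: Iterable[IonSpeciesDef], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([_ion_to_dict(i) for i in ions], indent=1))
        return
    rows = ["\t".join(_ION_FIELDS + ("loss_formula",))]
    for ion in ions:
        d = _ion_to_dict(ion)
        rows.append(
            "\t".join(str(d.get(k, "")) for k in _ION_FIELDS + ("loss_formula",))
        )
    path.write_text("\n".join(rows) + "\n")
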