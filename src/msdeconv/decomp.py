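"""Accurate-mass decomposition into candidate sum formulae.

A bounded recursive-descent enumerator over CHNOPS (heaviest element first,
branch-and-bound on the remaining mass) followed by a configurable filter
stack: element-number bounds, heuristic element-probability and
element-ratio checks, Senior and Lewis (RDBE) plausibility rules, an
oxygen/phosphorus ratio rule, plus two spectrum-aware constraints -- a
required sub-formula (from an observed neutral loss) and a fixed carbon
count (from a 13C labeling distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import MONOISOTOPIC_MASS, Formula

__all__ = [
    "ALL_FILTERS",
    "CHEMISTRY_FILTERS",
    "ElementBounds",
    "DecompositionQuery",
    "FilterReport",
    "default_bounds",
    "decompose",
    "passes_filters",
    "carbon_count_range",
]

#: Names of all supported filter flags.
ALL_FILTERS = frozenset(
    {
        "element_number",
        "element_probability",
        "element_ratio",
        "senior",
        "lewis",
        "oxygen_phosphorus",
    }
)
#: The pure chemistry filters (no spectrum-aware constraints involved).
CHEMISTRY_FILTERS = ALL_FILTERS

_VALENCE = {"C": 4, "H": 1, "N": 3, "O": 2, "P": 3, "S": 2}

#: Default count bounds for neutral masses below ~500 Da.
_DEFAULT_BOUNDS = {
    "C": (0, 39),
    "H": (0, 72),
    "N": (0, 20),
    "O": (0, 20),
    "P": (0, 9),
    "S": (0, 10),
}


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) count bounds."""

    bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.bounds.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")

    def elements(self) -> list[str]:
        return list(self.bounds)

    def range_of(self, el: str) -> tuple[int, int]:
        return self.bounds.get(el, (0, 0))


def default_bounds() -> ElementBounds:
    return ElementBounds()


@dataclass(frozen=True)
class DecompositionQuery:
    target_mass: float
    tolerance: float = 0.005
    bounds: ElementBounds = field(default_factory=default_bounds)
    fixed_carbon: int | None = None
    required_subformula: Formula | None = None
    filters: frozenset[str] = ALL_FILTERS

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        if self.fixed_carbon is not None and self.fixed_carbon < 0:
            raise ValueError("fixed_carbon must be >= 0")
        unknown = set(self.filters) - ALL_FILTERS
        if unknown:
            raise ValueError(f"unknown filter flags: {sorted(unknown)}")
        object.__setattr__(self, "filters", frozenset(self.filters))


@dataclass(frozen=True)
class FilterReport:
    formula: Formula
    failed_filters: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.failed_filters


# ----------------------------------------------------------------------
# individual filters
# ----------------------------------------------------------------------

def _check_element_number(f: Formula, q: DecompositionQuery) -> bool:
    for el in set(f) | set(q.bounds.elements()):
        lo, hi = q.bounds.range_of(el)
        if not (lo <= f.get(el) <= hi):
            return False
    return True


def _check_element_ratio(f: Formula, q: DecompositionQuery) -> bool:
    # Extended heteroatom-per-carbon ranges; trivially true for carbon-free
    # formulae (the ratios are undefined there).
    c = f.get("C")
    if c == 0:
        return True
    hc = f.get("H") / c
    if f.get("H") and not (0.1 <= hc <= 6.0):
        return False
    if f.get("N") / c > 4.0:
        return False
    if f.get("O") / c > 3.0:
        return False
    if f.get("P") / c > 2.0:
        return False
    if f.get("S") / c > 3.0:
        return False
    return True


def _check_element_probability(f: Formula, q: DecompositionQuery) -> bool:
    """Heuristic rejection of improbable multiple-heteroatom combinations."""
    n, o, p, s = f.get("N"), f.get("O"), f.get("P"), f.get("S")
    if n > 1 and o > 1 and p > 1 and s > 1:
        if not (n < 10 and o < 20 and p < 4 and s < 3):
            return False
    if n > 3 and o > 3 and p > 3:
        if not (n < 11 and o < 22 and p < 6):
            return False
    if o > 1 and p > 1 and s > 1:
        if not (o < 14 and p < 3 and s < 3):
            return False
    if p > 1 and s > 1:
        if not (p < 3 and s < 3):
            return False
    if n > 1 and s > 1:
        if not (n < 4 and s < 3):
            return False
    return True


def _check_senior(f: Formula, q: DecompositionQuery) -> bool:
    atoms = sum(f.values())
    if atoms == 0:
        return True
    vsum = sum(_VALENCE.get(el, 0) * n for el, n in f.items())
    if vsum % 2 != 0:
        return False
    return vsum >= 2 * (atoms - 1)


def _check_lewis(f: Formula, q: DecompositionQuery) -> bool:
    # RDBE = C - H/2 + N/2 + 1 must be a non-negative integer for
    # even-electron neutral molecules.
    rdbe2 = 2 * f.get("C") - f.get("H") + f.get("N") + 2
    return rdbe2 >= 0 and rdbe2 % 2 == 0


def _check_oxygen_phosphorus(f: Formula, q: DecompositionQuery) -> bool:
    p = f.get("P")
    if p == 0:
        return True
    return f.get("O") >= 3.3 * p


_FILTER_FUNCS = {
    "element_number": _check_element_number,
    "element_probability": _check_element_probability,
    "element_ratio": _check_element_ratio,
    "senior": _check_senior,
    "lewis": _check_lewis,
    "oxygen_phosphorus": _check_oxygen_phosphorus,
}


def passes_filters(f: Formula, q: DecompositionQuery) -> FilterReport:
    """Evaluate every active filter (plus the spectrum-aware constraints)
    independently and report which ones failed."""
    failed: list[str] = []
    for name in sorted(q.filters):
        if not _FILTER_FUNCS[name](f, q):
            failed.append(name)
    if q.fixed_carbon is not None and f.get("C") != q.fixed_carbon:
        failed.append("fixed_carbon")
    if q.required_subformula is not None and not f.contains(q.required_subformula):
        failed.append("required_subformula")
    return FilterReport(formula=f, failed_filters=tuple(failed))


# ----------------------------------------------------------------------
# enumeration
# ----------------------------------------------------------------------

def _effective_bounds(q: DecompositionQuery) -> list[tuple[str, int, int]]:
    items = []
    for el in q.bounds.elements():
        lo, hi = q.bounds.range_of(el)
        if q.required_subformula is not None:
            lo = max(lo, q.required_subformula.get(el))
        if el == "C" and q.fixed_carbon is not None:
            lo = hi = q.fixed_carbon
        # cap by mass: no point exceeding target+tol
        cap = int((q.target_mass + q.tolerance) / MONOISOTOPIC_MASS[el])
        hi = min(hi, cap) if el != "C" or q.fixed_carbon is None else hi
        items.append((el, lo, hi))
    # heaviest first; ties broken alphabetically for determinism
    items.sort(key=lambda t: (-MONOISOTOPIC_MASS[t[0]], t[0]))
    return items


def decompose(q: DecompositionQuery) -> list[Formula]:
    """All formulae within ``tolerance`` of ``target_mass`` that satisfy the
    bounds, spectrum-aware constraints and every active filter.

    Result is complete (identical to brute-force enumeration over the
    bounds) and ordered by absolute mass error, ties by Hill string.
    """
    if q.target_mass <= 0:
        raise ValueError(f"target mass must be positive, got {q.target_mass}")
    order = _effective_bounds(q)
    n_el = len(order)
    # min/max achievable mass for the remaining suffix of elements
    suffix_min = [0.0] * (n_el + 1)
    suffix_max = [0.0] * (n_el + 1)
    for i in range(n_el - 1, -1, -1):
        el, lo, hi = order[i]
        m = MONOISOTOPIC_MASS[el]
        suffix_min[i] = suffix_min[i + 1] + lo * m
        suffix_max[i] = suffix_max[i + 1] + hi * m

    results: list[tuple[float, str, Formula]] = []
    counts: dict[str, int] = {}

    def recurse(i: int, remaining: float) -> None:
        if i == n_el:
            if abs(remaining) <= q.tolerance:
                f = Formula(counts)
                if passes_filters(f, q).passed:
                    results.append((abs(remaining), f.hill(), f))
            return
        el, lo, hi = order[i]
        m = MONOISOTOPIC_MASS[el]
        for n in range(lo, hi + 1):
            rest = remaining - n * m
            if rest < suffix_min[i + 1] - q.tolerance:
                break  # counts only grow from here
            if rest > suffix_max[i + 1] + q.tolerance:
                continue
            counts[el] = n
            recurse(i + 1, rest)
        counts.pop(el, None)

    recurse(0, q.target_mass)
    results.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in results]


def carbon_count_range(
    neutral_mass: float,
    tolerance: float = 0.005,
    bounds: ElementBounds | None = None,
    filters: Iterable[str] = CHEMISTRY_FILTERS,
) -> set[int]:
    """Set of plausible carbon counts for a neutral mass, from decomposition
    with the chemistry filters active.  May be empty."""
    q = DecompositionQuery(
        target_mass=neutral_mass,
        tolerance=tolerance,
        bounds=bounds if bounds is not None else default_bounds(),
        filters=frozenset(filters),
    )
    return {f.get("C") for f in decompose(q)}
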