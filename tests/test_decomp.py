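"""Decomposition tests, including an independent brute-force oracle.

The oracle enumerates all formulae over (reduced) bounds with vectorized
numpy and re-implements every filter as straight-line checks, separate from
the library's implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msdeconv.chem import MONOISOTOPIC_MASS, Formula, parse_formula
from msdeconv.decomp import (
    ALL_FILTERS,
    DecompositionQuery,
    ElementBounds,
    carbon_count_range,
    decompose,
    default_bounds,
    passes_filters,
)

# -- independent oracle -------------------------------------------------

ORACLE_BOUNDS = {
    "C": (0, 20),
    "H": (0, 40),
    "N": (0, 8),
    "O": (0, 12),
    "P": (0, 3),
    "S": (0, 3),
}
_ELS = list(ORACLE_BOUNDS)


def _oracle_grid():
    ranges = [np.arange(lo, hi + 1) for lo, hi in ORACLE_BOUNDS.values()]
    grids = np.meshgrid(*ranges, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)
    masses = counts @ np.array([MONOISOTOPIC_MASS[e] for e in _ELS])
    return counts, masses


_GRID_COUNTS, _GRID_MASSES = _oracle_grid()


def oracle_filter_ok(c: dict, active) -> bool:
    C, H, N, O, P, S = (c.get(e, 0) for e in "CHNOPS")
    if "element_ratio" in active and C > 0:
        if H > 0 and not (0.1 <= H / C <= 6):
            return False
        if N / C > 4 or O / C > 3 or P / C > 2 or S / C > 3:
            return False
    if "element_probability" in active:
        if N > 1 and O > 1 and P > 1 and S > 1 and not (N < 10 and O < 20 and P < 4 and S < 3):
            return False
        if N > 3 and O > 3 and P > 3 and not (N < 11 and O < 22 and P < 6):
            return False
        if O > 1 and P > 1 and S > 1 and not (O < 14 and P < 3 and S < 3):
            return False
        if P > 1 and S > 1 and not (P < 3 and S < 3):
            return False
        if N > 1 and S > 1 and not (N < 4 and S < 3):
            return False
    if "senior" in active:
        val = 4 * C + H + 3 * N + 2 * O + 3 * P + 2 * S
        atoms = C + H + N + O + P + S
        if val % 2 == 1:
            return False
        if atoms and val < 2 * (atoms - 1):
            return False
    if "lewis" in active:
        rdbe2 = 2 * C - H + N + 2
        if rdbe2 < 0 or rdbe2 % 2 == 1:
            return False
    if "oxygen_phosphorus" in active and P > 0 and O < 3.3 * P:
        return False
    return True


def oracle_decompose(mass, tol, active=ALL_FILTERS, fixed_carbon=None, required=None):
    sel = np.abs(_GRID_MASSES - mass) <= tol
    out = set()
    for row in _GRID_COUNTS[sel]:
        c = dict(zip(_ELS, (int(v) for v in row)))
        if fixed_carbon is not None and c.get("C", 0) != fixed_carbon:
            continue
        if required is not None and any(
            c.get(e, 0) < n for e, n in required.items()
        ):
            continue
        if oracle_filter_ok(c, active):
            out.add(Formula({e: n for e, n in c.items() if n}))
    return out


ORACLE_EB = ElementBounds(dict(ORACLE_BOUNDS))


class TestDecomposeExamples:
    def test_glutamate_unique_with_carbon_filter(self):
        res = decompose(
            DecompositionQuery(147.052, 0.005, fixed_carbon=5)
        )
        assert [f.hill() for f in res] == ["C5H9NO4"]

    def test_water_found(self):
        res = decompose(DecompositionQuery(18.0106, 0.002))
        assert parse_formula("H2O") in res

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            decompose(DecompositionQuery(-5.0, 0.005))

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError):
            DecompositionQuery(100.0, 0.0)

    def test_results_sorted_by_error(self):
        res = decompose(DecompositionQuery(147.052, 0.01, filters=frozenset()))
        errs = [abs(f.mass - 147.052) for f in res]
        assert errs == sorted(errs)

    def test_every_result_within_tolerance(self):
        q = DecompositionQuery(250.1, 0.01)
        for f in decompose(q):
            assert abs(f.mass - q.target_mass) <= q.tolerance


class TestFilters:
    def test_oxygen_phosphorus_rule(self):
        q = DecompositionQuery(100.0, 0.1, filters=frozenset({"oxygen_phosphorus"}))
        rep = passes_filters(Formula({"C": 1, "P": 1, "O": 1}), q)
        assert not rep.passed and "oxygen_phosphorus" in rep.failed_filters

    def test_required_subformula(self):
        q = DecompositionQuery(
            200.0, 0.1, filters=frozenset(),
            required_subformula=parse_formula("C6H12O6"),
        )
        rep = passes_filters(parse_formula("C5H9NO4"), q)
        assert "required_subformula" in rep.failed_filters
        ok = passes_filters(parse_formula("C7H14O7"), q)
        assert ok.passed

    def test_fixed_carbon(self):
        q = DecompositionQuery(147.0, 0.1, filters=frozenset(), fixed_carbon=15)
        rep = passes_filters(parse_formula("C5H9NO4"), q)
        assert rep.failed_filters == ("fixed_carbon",)

    def test_passed_iff_no_failures(self):
        q = DecompositionQuery(147.052, 0.005)
        rep = passes_filters(parse_formula("C5H9NO4"), q)
        assert rep.passed and rep.failed_filters == ()

    def test_lewis_rejects_odd_hydrogen_parity(self):
        q = DecompositionQuery(100.0, 0.1, filters=frozenset({"lewis"}))
        assert not passes_filters(Formula({"C": 5, "H": 9}), q).passed
        assert passes_filters(Formula({"C": 5, "H": 10}), q).passed

    def test_senior_rejects_odd_valence_sum(self):
        q = DecompositionQuery(100.0, 0.1, filters=frozenset({"senior"}))
        assert not passes_filters(Formula({"C": 1, "H": 3}), q).passed
        assert passes_filters(Formula({"C": 1, "H": 4}), q).passed


class TestCarbonCountRange:
    def test_glutamate_mass_contains_five(self):
        assert 5 in carbon_count_range(147.0532, 0.005)

    def test_methane_unique(self):
        assert carbon_count_range(16.0313, 0.002) == {1}

    def test_below_lightest_formula_empty(self):
        assert carbon_count_range(1.0, 0.0001) == set()

    def test_matches_oracle(self):
        got = carbon_count_range(147.0532, 0.005, ORACLE_EB)
        want = {f.get("C") for f in oracle_decompose(147.0532, 0.005)}
        assert got == want


class TestOracleEquivalence:
    @pytest.mark.parametrize("mass", [59.0371, 147.0532, 180.0634, 255.0297])
    def test_known_masses(self, mass):
        got = set(decompose(DecompositionQuery(mass, 0.005, bounds=ORACLE_EB)))
        assert got == oracle_decompose(mass, 0.005)

    def test_random_masses(self):
        rng = np.random.default_rng(42)
        for mass in rng.uniform(40.0, 400.0, size=25):
            got = set(decompose(DecompositionQuery(mass, 0.005, bounds=ORACLE_EB)))
            want = oracle_decompose(mass, 0.005)
            assert got == want, f"mismatch at mass {mass}"

    def test_random_masses_no_filters(self):
        rng = np.random.default_rng(7)
        for mass in rng.uniform(40.0, 250.0, size=10):
            got = set(
                decompose(
                    DecompositionQuery(
                        mass, 0.005, bounds=ORACLE_EB, filters=frozenset()
                    )
                )
            )
            want = oracle_decompose(mass, 0.005, active=frozenset())
            assert got == want

    def test_fixed_carbon_and_subformula(self):
        req = parse_formula("H2O")
        got = set(
            decompose(
                DecompositionQuery(
                    180.0634, 0.005, bounds=ORACLE_EB,
                    fixed_carbon=6, required_subformula=req,
                )
            )
        )
        want = oracle_decompose(180.0634, 0.005, fixed_carbon=6, required=req)
        assert got == want


class TestMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(mass=st.floats(min_value=50.0, max_value=350.0))
    def test_larger_tolerance_is_superset(self, mass):
        small = set(decompose(DecompositionQuery(mass, 0.002, bounds=ORACLE_EB)))
        large = set(decompose(DecompositionQuery(mass, 0.008, bounds=ORACLE_EB)))
        assert small <= large

    @settings(max_examples=25, deadline=None)
    @given(mass=st.floats(min_value=50.0, max_value=350.0))
    def test_adding_filter_never_adds_results(self, mass):
        loose = set(
            decompose(
                DecompositionQuery(mass, 0.005, bounds=ORACLE_EB, filters=frozenset())
            )
        )
        strict = set(decompose(DecompositionQuery(mass, 0.005, bounds=ORACLE_EB)))
        assert strict <= loose
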