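import numpy as np
import pytest

from msdeconv.chem import C13_DELTA, ion_mz, parse_formula
from msdeconv.pipeline import SDConfig, deconvolve, detect_isotope_chains, eic_correlation
from msdeconv.simulate import (
    GroundTruthCompound,
    NoiseModel,
    build_preset,
    evaluate_recovery,
    mirrored_pattern,
    natural_isotope_pattern,
    preset_scenarios,
    simulate_eics,
    simulate_peak_table,
)


class TestNaturalPattern:
    def test_c5_m_plus_one(self):
        pat = natural_isotope_pattern(parse_formula("C5H9NO4"), 2)
        assert pat[0] == 1.0
        assert pat[1] == pytest.approx(0.054, abs=1e-3)

    def test_carbon_free_no_satellites(self):
        assert natural_isotope_pattern(parse_formula("H2O"), 3) == [1.0, 0.0, 0.0]

    def test_k1(self):
        assert natural_isotope_pattern(parse_formula("C6H12O6"), 1) == [1.0]

    def test_strictly_decreasing_up_to_large_carbon(self):
        pat = natural_isotope_pattern(parse_formula("C39H72"), 5)
        assert all(a > b for a, b in zip(pat, pat[1:]))

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            natural_isotope_pattern(parse_formula("C5H9NO4"), 0)


class TestMirroredPattern:
    def test_c5_purity_099(self):
        pat = mirrored_pattern(parse_formula("C5H9NO4"), 2, purity=0.99)
        assert pat[1] == pytest.approx(0.051, abs=2e-3)

    def test_full_purity_single_peak(self):
        assert mirrored_pattern(parse_formula("C5H9NO4"), 3, purity=1.0) == [1.0, 0.0, 0.0]

    def test_carbon_free_single_peak(self):
        assert mirrored_pattern(parse_formula("H2O"), 2, purity=0.99) == [1.0, 0.0]

    def test_bad_purity_rejected(self):
        with pytest.raises(ValueError):
            mirrored_pattern(parse_formula("C5H9NO4"), 2, purity=0.0)


class TestSimulatePeakTable:
    def test_determinism(self):
        compounds, cfg = build_preset("glutamate")
        nm = NoiseModel(seed=42, mz_sd=0.001, intensity_cv=0.1, n_contaminant_peaks=5)
        p1, t1 = simulate_peak_table(compounds, nm)
        p2, t2 = simulate_peak_table(compounds, nm)
        assert [(p.id, p.mz, p.rt, p.maxo) for p in p1] == [
            (p.id, p.mz, p.rt, p.maxo) for p in p2
        ]
        assert t1 == t2

    def test_truth_covers_all_non_contaminants(self):
        compounds, cfg = build_preset("glutamate")
        peaks, truth = simulate_peak_table(
            compounds, NoiseModel(seed=1, n_contaminant_peaks=10)
        )
        untracked = [p.id for p in peaks if p.id not in truth]
        assert len(untracked) == 10  # exactly the contaminants

    def test_contaminants_only(self):
        comp = GroundTruthCompound(
            "dummy", parse_formula("C5H9NO4"), rt=100.0,
            species=[(build_preset("glutamate")[1].ion_list[0], 1.0)],
        )
        peaks, truth = simulate_peak_table(
            [comp], NoiseModel(seed=3, n_contaminant_peaks=10)
        )
        orphan_candidates = [p for p in peaks if p.id not in truth]
        assert len(orphan_candidates) == 10

    def test_empty_compound_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_peak_table([], NoiseModel())

    def test_zero_noise_chains_satisfy_rules(self):
        compounds, cfg = build_preset("glutamate")
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=0))
        by_id = {p.id: p for p in peaks}
        chains = detect_isotope_chains(peaks, cfg)
        for ch in chains:
            sign = -1 if ch.mirrored else 1
            for a, b in zip(ch.members, ch.members[1:]):
                d = (by_id[b].mz - by_id[a].mz) * sign
                assert abs(d - C13_DELTA / ch.charge) <= cfg.eps_mz
                assert by_id[b].maxo < by_id[a].maxo * cfg.intensity_slack

    def test_glutamate_primary_mz(self):
        compounds, cfg = build_preset("glutamate")
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=0))
        prim = next(
            p for p in peaks
            if truth.get(p.id)
            and truth[p.id].species_label == "[M+H]+"
            and truth[p.id].isotope_index == 0
        )
        assert prim.mz == pytest.approx(148.0604, abs=1e-3)

    def test_dipeptide_fragment_pair(self):
        compounds, cfg = build_preset("glu_met_dipeptide")
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=0))
        frag12 = next(
            p for p in peaks
            if truth.get(p.id)
            and truth[p.id].species_label == "[M+H-C5H7NO3]+"
            and truth[p.id].isotope_index == 0
        )
        assert frag12.mz == pytest.approx(150.0583, abs=1e-3)
        frag13 = next(
            p for p in peaks
            if truth.get(p.id)
            and truth[p.id].labeled
            and truth[p.id].shift == 5
            and truth[p.id].isotope_index == 0
        )
        assert frag13.mz - frag12.mz == pytest.approx(5 * C13_DELTA, abs=1e-9)


class TestSimulateEics:
    def test_same_compound_correlates(self):
        compounds, cfg = build_preset("glutamate")
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=0))
        simulate_eics(peaks, truth, compounds)
        a = next(p for p in peaks if truth[p.id].species_label == "[M+H]+" and truth[p.id].isotope_index == 0)
        b = next(p for p in peaks if truth[p.id].species_label == "[M+Na]+" and truth[p.id].isotope_index == 0)
        assert eic_correlation(a, b) >= 0.999

    def test_separated_compounds_decorrelate(self):
        ions = build_preset("glutamate")[1].ion_list
        sp = {i.label: i for i in ions}
        c1 = GroundTruthCompound(
            "one", parse_formula("C5H9NO4"), rt=100.0, rt_sigma=3.0,
            species=[(sp["[M+H]+"], 1.0)],
        )
        c2 = GroundTruthCompound(
            "two", parse_formula("C6H12O6"), rt=109.0, rt_sigma=3.0,
            species=[(sp["[M+H]+"], 1.0)],
        )
        peaks, truth = simulate_peak_table([c1, c2], NoiseModel(seed=0))
        simulate_eics(peaks, truth, [c1, c2])
        a = next(p for p in peaks if truth[p.id].compound == "one" and truth[p.id].isotope_index == 0)
        b = next(p for p in peaks if truth[p.id].compound == "two" and truth[p.id].isotope_index == 0)
        assert eic_correlation(a, b) < 0.5

    def test_zero_grid_rejected(self):
        compounds, cfg = build_preset("glutamate")
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=0))
        with pytest.raises(ValueError):
            simulate_eics(peaks, truth, compounds, dt=0.0)


class TestPresets:
    def test_four_presets_listed(self):
        names = set(preset_scenarios())
        assert names == {
            "glutamate",
            "glu_met_dipeptide",
            "coeluting_pair",
            "unlabeled_standard_missing",
        }

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            build_preset("nope")

    @pytest.mark.parametrize("name", sorted(preset_scenarios()))
    def test_all_presets_fully_recovered_at_zero_noise(self, name):
        compounds, cfg = build_preset(name)
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=123))
        rec = evaluate_recovery(deconvolve(peaks, cfg), truth)
        for cat, (got, want) in rec.items():
            assert got == want, f"{name}/{cat}: {got}/{want}"

    def test_unlabeled_preset_has_no_label_peaks(self):
        compounds, cfg = build_preset("unlabeled_standard_missing")
        peaks, truth = simulate_peak_table(compounds, NoiseModel(seed=0))
        assert not any(rec.labeled for rec in truth.values())


class TestNoisyRecovery:
    def test_recovery_rate_above_95_percent(self):
        # aggregate over seeded runs at mz noise eps/3
        got = want = 0
        for seed in range(40):
            compounds, cfg = build_preset("glutamate")
            peaks, truth = simulate_peak_table(
                compounds, NoiseModel(seed=seed, mz_sd=cfg.eps_mz / 3)
            )
            rec = evaluate_recovery(deconvolve(peaks, cfg), truth)
            for g, w in rec.values():
                got += g
                want += w
        assert want > 0
        assert got / want >= 0.95, f"recovered {got}/{want}"
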