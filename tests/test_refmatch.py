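import math

import numpy as np
import pytest

from msdeconv.pipeline import deconvolve
from msdeconv.refmatch import (
    ReferenceList,
    apply_reference_list,
    create_reference_list,
    dot_product_score,
    match_record_file,
    parse_massbank_record,
    pseudo_fragment_spectrum,
)
from msdeconv.simulate import NoiseModel, build_preset, simulate_peak_table


class TestDotProduct:
    def test_identical_is_one(self):
        a = [(100.0, 1.0), (150.0, 0.5), (200.0, 0.1)]
        assert dot_product_score(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_is_zero(self):
        assert dot_product_score([(100.0, 1.0)], [(300.0, 1.0)]) == 0.0

    def test_hand_computed_value(self):
        # cross = 1, norms = sqrt(1.25) and 1 -> 1/sqrt(1.25) = 0.894
        a = [(100.0, 1.0), (150.0, 0.5)]
        b = [(100.0, 1.0)]
        assert round(dot_product_score(a, b), 3) == 0.894

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = [(float(m), float(i)) for m, i in zip(rng.uniform(50, 500, 8), rng.uniform(0.1, 1, 8))]
        b = [(float(m), float(i)) for m, i in zip(rng.uniform(50, 500, 6), rng.uniform(0.1, 1, 6))]
        assert dot_product_score(a, b) == pytest.approx(
            dot_product_score(b, a), abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dot_product_score([], [(100.0, 1.0)])


class TestPseudoFragmentSpectrum:
    def test_glutamate_members(self, glutamate_run):
        peaks, truth, cfg, result = glutamate_run
        by_id = {p.id: p for p in peaks}
        spec = next(s for s in result.spectra if abs(s.M - 147.0532) < 0.005)
        frag = pseudo_fragment_spectrum(spec, by_id)
        labels = {p[2] for p in frag}
        assert "[M+H]+" in labels
        assert "[M+H-H2O]+" in labels and "[M+H-HCOOH]+" in labels
        # adducts, homoadducts and 13C peaks excluded
        assert not labels & {"[M+Na]+", "[M+K]+", "[2M+H]+", "[M+5+H]+", "[2M+5+H]+"}
        assert max(p[1] for p in frag) == pytest.approx(1.0)

    def test_no_pseudomolecular_ion_raises(self, glutamate_run):
        peaks, truth, cfg, result = glutamate_run
        import copy

        by_id = {p.id: p for p in peaks}
        spec = copy.deepcopy(next(s for s in result.spectra if abs(s.M - 147.0532) < 0.005))
        spec.annotations = [a for a in spec.annotations if a.ion_label != "[M+H]+"]
        with pytest.raises(ValueError):
            pseudo_fragment_spectrum(spec, by_id)

    def test_lone_pseudomolecular_ion(self, glutamate_run):
        peaks, truth, cfg, result = glutamate_run
        by_id = {p.id: p for p in peaks}
        spec = next(s for s in result.spectra if abs(s.M - 147.0532) < 0.005)
        import copy

        spec = copy.deepcopy(spec)
        spec.annotations = [a for a in spec.annotations if a.ion_label == "[M+H]+"]
        assert len(pseudo_fragment_spectrum(spec, by_id)) == 1


@pytest.fixture()
def confirmed_run(glutamate_run):
    import copy

    peaks, truth, cfg, result = glutamate_run
    result = copy.deepcopy(result)
    spec = next(s for s in result.spectra if abs(s.M - 147.0532) < 0.005)
    spec.status = "confirmed"
    spec.compound_name = "glutamate"
    return peaks, cfg, result, spec


class TestCreateReferenceList:
    def test_single_confirmed_entry(self, confirmed_run):
        peaks, cfg, result, spec = confirmed_run
        ref = create_reference_list(result.spectra, peaks, name="test")
        assert len(ref.entries) == 1
        entry = ref.entries[0]
        assert entry.compound == "glutamate"
        labels = {p[2] for p in entry.peaks}
        assert "[M+H]+" in labels and "[M+Na]+" in labels
        # 13C peaks excluded
        assert not any("+5" in l for l in labels)

    def test_unconfirmed_skipped(self, glutamate_run):
        peaks, truth, cfg, result = glutamate_run
        ref = create_reference_list(result.spectra, peaks)
        assert ref.entries == []

    def test_json_round_trip(self, confirmed_run, tmp_path):
        peaks, cfg, result, spec = confirmed_run
        ref = create_reference_list(result.spectra, peaks, name="rt")
        path = tmp_path / "ref.json"
        ref.save(path)
        back = ReferenceList.load(path)
        assert back.name == "rt" and len(back.entries) == 1
        assert back.entries[0].peaks == ref.entries[0].peaks


class TestApplyReferenceList:
    def test_source_chromatogram_rescored_at_one(self, confirmed_run):
        peaks, cfg, result, spec = confirmed_run
        ref = create_reference_list(result.spectra, peaks)
        # fresh deconvolution of the same chromatogram
        res2 = deconvolve(peaks, cfg)
        out = apply_reference_list(ref, res2.spectra, peaks, cfg)
        assert len(out) == 1
        assert out[0]["score"] == pytest.approx(1.0, abs=1e-9)
        annotated = next(s for s in res2.spectra if s.id == out[0]["spectrum"])
        assert annotated.compound_name == "glutamate"
        assert annotated.status == "confirmed"

    def test_jittered_intensities_still_match(self, confirmed_run):
        peaks, cfg, result, spec = confirmed_run
        ref = create_reference_list(result.spectra, peaks, score_threshold=0.8)
        import copy

        rng = np.random.default_rng(5)
        jittered = copy.deepcopy(peaks)
        for p in jittered:
            f = float(rng.uniform(0.9, 1.1))
            p.maxo *= f
            p.into *= f
            p.intb *= f
        res2 = deconvolve(jittered, cfg)
        out = apply_reference_list(ref, res2.spectra, jittered, cfg)
        assert out[0]["score"] >= 0.95 and out[0]["spectrum"] is not None

    def test_outside_rt_tolerance_not_annotated(self, confirmed_run):
        peaks, cfg, result, spec = confirmed_run
        ref = create_reference_list(result.spectra, peaks, rt_tolerance=5.0)
        import copy

        shifted = copy.deepcopy(peaks)
        for p in shifted:
            p.rt += 100.0
            p.rt_min += 100.0
            p.rt_max += 100.0
        res2 = deconvolve(shifted, cfg)
        out = apply_reference_list(ref, res2.spectra, shifted, cfg)
        assert out[0]["spectrum"] is None

    def test_assembly_mode_builds_spectrum(self, confirmed_run):
        peaks, cfg, result, spec = confirmed_run
        ref = create_reference_list(result.spectra, peaks)
        spectra: list = []  # no prior deconvolution
        out = apply_reference_list(ref, spectra, peaks, cfg)
        assert out[0]["assembled"] and len(spectra) == 1
        assert spectra[0].compound_name == "glutamate"


MASSBANK_RECORD = """ACCESSION: XX000001
RECORD_TITLE: Glutamic acid; LC-ESI-QTOF; MS2
CH$NAME: Glutamic acid
PK$NUM_PEAK: 3
PK$PEAK: m/z int. rel.int.
  84.0444 200000 999
  102.0550 80000 400
  130.0499 60000 300
//
"""


class TestMatchRecordFile:
    def test_parse(self, tmp_path):
        path = tmp_path / "rec1.txt"
        path.write_text(MASSBANK_RECORD)
        name, peaks = parse_massbank_record(path)
        assert name == "Glutamic acid; LC-ESI-QTOF; MS2"
        assert len(peaks) == 3
        assert peaks[0][1] == pytest.approx(1.0)

    def test_identical_record_ranks_first(self, tmp_path):
        p1 = tmp_path / "match.txt"
        p1.write_text(MASSBANK_RECORD)
        p2 = tmp_path / "other.txt"
        p2.write_text(
            MASSBANK_RECORD.replace("84.0444", "500.1").replace("102.0550", "600.2").replace("130.0499", "700.3")
        )
        query = [(84.0444, 1.0), (102.0550, 0.4), (130.0499, 0.3)]
        ranked = match_record_file(query, [p1, p2])
        # MassBank rel.int. is integer-scaled (999), so normalization is
        # only approximately exact
        assert ranked[0][1] == pytest.approx(1.0, abs=1e-6)
        assert ranked[1][1] == 0.0

    def test_unparseable_skipped(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("nothing useful here\n")
        good = tmp_path / "good.txt"
        good.write_text(MASSBANK_RECORD)
        ranked = match_record_file([(84.0444, 1.0)], [bad, good])
        assert len(ranked) == 1

    def test_empty_directory_empty_ranking(self):
        assert match_record_file([(84.0444, 1.0)], []) == []
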