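"""CID rule engine: every published worked example, plus grammar
round-trip, decoy robustness and determinism properties."""

import numpy as np
import pytest

from amphiscan import (
    Spectrum,
    annotate,
    detect_carbonyl_pairs,
    detect_sulfation,
    detect_terminus_loss,
    match_known,
)
from amphiscan.cid_annotator import assign_arm, classify_hydrophilic_type
from amphiscan.spectra_io import TransitionEntry, TransitionTable
from amphiscan.synthetic_data import make_spectrum, random_variant_spec


class TestSulfation:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("ARC-2", 1146.0),
            ("ARC-4", 1278.0),
            ("ARC-6", 1326.0),
            ("ARC-8", 1488.0),
        ],
    )
    def test_sulfated_variants_lose_120(self, arc_spectra, name, expected):
        res = detect_sulfation(arc_spectra[name])
        assert res.sulfated
        assert res.desulfated_mz == expected

    @pytest.mark.parametrize("name", ["ARC-1", "ARC-3", "ARC-5", "ARC-7"])
    def test_non_sulfated_variants(self, arc_spectra, name):
        res = detect_sulfation(arc_spectra[name])
        assert not res.sulfated
        assert res.desulfated_mz is None


class TestArmAssignment:
    @pytest.mark.parametrize(
        "name,arm,cleavage",
        [
            ("ARC-1", 392.0, 834.0),
            ("ARC-2", 392.0, 754.0),
            ("ARC-3", 426.0, 932.0),
            ("ARC-4", 392.0, 886.0),
            ("ARC-5", 392.0, 1034.0),
            ("ARC-6", 398.0, 928.0),
            ("ARC-7", 426.0, 1080.0),
            ("ARC-8", 426.0, 1062.0),
        ],
    )
    def test_fixture_arm_assignments(self, arc_spectra, name, arm, cleavage):
        s = arc_spectra[name]
        result = assign_arm(s, detect_sulfation(s))
        assert result == (arm, cleavage)

    def test_no_arm_consistent_fragment_absent(self):
        s = Spectrum("none", 1300.0, 3.0, ((700.0, 100.0), (1300.0, 10.0)))
        assert assign_arm(s, detect_sulfation(s)) is None


class TestCarbonylPairs:
    def test_arc7_pair_series(self, arc_spectra):
        pairs = detect_carbonyl_pairs(
            arc_spectra["ARC-7"].fragments, precursor_mz=1506.0
        )
        assert pairs == [(1288.0, 1230.0), (862.0, 804.0)]

    def test_am18_worked_example(self):
        frags = tuple((m, 100.0) for m in (687.0, 745.0, 963.0, 1105.0, 1163.0))
        pairs = detect_carbonyl_pairs(frags)
        assert pairs == [(1163.0, 1105.0), (745.0, 687.0)]
        assert all(hi - lo == pytest.approx(58.0) for hi, lo in pairs)

    def test_no_pairs_when_spacing_absent(self):
        assert detect_carbonyl_pairs(((100.0, 1.0), (200.0, 1.0))) == []

    def test_precursor_excluded_from_pairing(self):
        frags = ((942.0, 100.0), (1000.0, 50.0))
        assert detect_carbonyl_pairs(frags, precursor_mz=1000.0) == []


class TestTerminusLoss:
    def test_arc7_218_from_precursor(self, arc_spectra):
        s = arc_spectra["ARC-7"]
        assert detect_terminus_loss(s, detect_sulfation(s)) == 218.0

    def test_arc8_200_from_desulfated(self, arc_spectra):
        s = arc_spectra["ARC-8"]
        assert detect_terminus_loss(s, detect_sulfation(s)) == 200.0

    def test_neither_loss_returns_none(self, arc_spectra):
        s = arc_spectra["ARC-1"]
        assert detect_terminus_loss(s, detect_sulfation(s)) is None

    def test_218_takes_precedence_over_200(self):
        # sulfated spectrum carrying both losses
        s = Spectrum(
            "both",
            1500.0,
            3.0,
            ((1180.0, 300.0), (1282.0, 400.0), (1380.0, 500.0), (1500.0, 50.0)),
        )
        sulf = detect_sulfation(s)
        assert sulf.sulfated
        assert detect_terminus_loss(s, sulf) == 218.0


class TestHydrophilicType:
    def test_arc1_base_peak_cleavage_is_lpd_type(self, arc_spectra):
        s = arc_spectra["ARC-1"]
        rec = annotate(s)
        assert rec.hydrophilic_type == {"LP-D-type"}

    def test_arc5_pairs_plus_terminus_is_am18_type(self, arc_spectra):
        rec = annotate(arc_spectra["ARC-5"])
        assert rec.hydrophilic_type == {"AM-18-type"}

    def test_no_cleavage_fragment_no_lpd_label(self):
        s = Spectrum("x", 1300.0, 3.0, ((700.0, 100.0), (1300.0, 10.0)))
        assert classify_hydrophilic_type(s, None) == frozenset()


class TestKnownMatch:
    TABLE = TransitionTable([TransitionEntry("ARC-1", 1226, 834, 3.89, False)])

    def test_table_row_matches(self, arc_spectra):
        assert match_known(arc_spectra["ARC-1"], self.TABLE) == "ARC-1"

    def test_tight_rt_tolerance_blocks_match(self, arc_spectra):
        table = TransitionTable([TransitionEntry("ARC-1", 1226, 834, 3.95, False)])
        assert match_known(arc_spectra["ARC-1"], table, rt_tol=0.01) is None

    def test_empty_table_absent(self, arc_spectra):
        assert match_known(arc_spectra["ARC-1"], TransitionTable([])) is None


class TestAnnotate:
    def test_fixture_panel_all_novel_against_known_library(self, fixture_set):
        spectra, known = fixture_set
        verdicts = [annotate(s, transition_table=known).verdict for s in spectra]
        assert verdicts == ["novel"] * 8

    def test_self_match_gives_known_verdict(self, arc_spectra):
        table = TransitionTable([TransitionEntry("ARC-1", 1226, 834, 3.89, False)])
        rec = annotate(arc_spectra["ARC-1"], transition_table=table)
        assert rec.verdict == "known:ARC-1"

    def test_rule_free_spectrum_is_non_am(self):
        # fragments placed away from every rule-consistent position
        s = Spectrum(
            "noise",
            1300.0,
            3.0,
            ((303.0, 50.0), (517.0, 80.0), (729.0, 60.0), (1300.0, 10.0)),
        )
        rec = annotate(s)
        assert rec.verdict == "non-AM"
        assert rec.evidence == []

    def test_record_invariants_hold_exactly_on_clean_spectra(self, fixture_set):
        spectra, known = fixture_set
        for s in spectra:
            rec = annotate(s, transition_table=known)
            if rec.sulfated:
                assert rec.desulfated_mz == s.precursor_mz - 120.0
            if rec.arm_mass is not None:
                base = rec.desulfated_mz if rec.sulfated else s.precursor_mz
                assert rec.cleavage_fragment_mz == base - rec.arm_mass
            for hi, lo in rec.carbonyl_pairs:
                assert hi - lo == pytest.approx(58.0, abs=1e-9)


class TestGrammarRoundTrip:
    def _assert_flags_recovered(self, spec, rec):
        assert rec.sulfated == spec.sulfated, spec
        assert rec.arm_mass == spec.arm_mass, spec
        assert bool(rec.carbonyl_pairs) == spec.has_carbonyl, spec
        if spec.terminus is None:
            assert rec.terminus_loss is None, spec
        else:
            assert rec.terminus_loss == spec.terminus, spec

    def test_flag_recovery_on_500_random_specs_zero_decoys(self):
        rng = np.random.default_rng(1234)
        for k in range(500):
            spec = random_variant_spec(rng, name=f"g{k}")
            rec = annotate(make_spectrum(spec, n_decoys=0, seed=rng))
            self._assert_flags_recovered(spec, rec)
            assert rec.verdict == "novel"

    def test_flag_recovery_robust_to_five_decoys(self):
        rng = np.random.default_rng(99)
        for k in range(500):
            spec = random_variant_spec(rng, name=f"d{k}")
            rec = annotate(make_spectrum(spec, n_decoys=5, seed=rng))
            self._assert_flags_recovered(spec, rec)

    def test_annotation_is_deterministic(self):
        rng = np.random.default_rng(5)
        spec = random_variant_spec(rng, "det")
        s = make_spectrum(spec, n_decoys=5, seed=11)
        first = annotate(s)
        for _ in range(3):
            again = annotate(s)
            assert again == first
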