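"""Three-mode screening: NL channels, brute-force equivalence, FS windows,
SRM matching and the robust S/N estimator."""

import math

import numpy as np
import pytest

from amphiscan import (
    Spectrum,
    build_nl_library,
    estimate_snr,
    fs_screen,
    nl_screen,
    srm_detect,
)
from amphiscan.screening import NLChannel, SrmPeak, fragment_snr
from amphiscan.spectra_io import TransitionEntry, TransitionTable, ValidationError
from amphiscan.synthetic_data import make_spectrum, random_variant_spec


def _spec(precursor, frags, rt=3.0, sid="s"):
    return Spectrum(sid, precursor, rt, tuple((m, i) for m, i in frags))


class TestNLLibrary:
    def test_default_library_has_fourteen_channels(self):
        channels = build_nl_library("default")
        assert len(channels) == 14
        assert sum(not c.sulfated for c in channels) == 7
        assert sum(c.sulfated for c in channels) == 7
        published = {c.loss_da for c in channels if c.provenance == "main_text"}
        assert published == {392.0, 398.0, 426.0}
        # the unpublished channels are explicitly flagged
        assert sum(c.provenance == "placeholder" for c in channels) == 4

    def test_custom_config_builds_requested_channels(self):
        channels = build_nl_library({"non_sulfated": [392, 398, 426]})
        assert len(channels) == 3
        assert {c.loss_da for c in channels} == {392.0, 398.0, 426.0}

    def test_duplicate_masses_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_nl_library({"non_sulfated": [392, 392]})


class TestNLScreen:
    ARM_392 = [NLChannel(392.0, False, "arm-392")]
    ARM_426 = [NLChannel(426.0, False, "arm-426")]

    def test_arm_loss_from_precursor_1226_hits(self):
        s = _spec(1226, [(834, 1000), (1226, 50)])
        hits = nl_screen(s, self.ARM_392)
        assert len(hits) == 1
        assert hits[0].q1_mz == 1226
        assert hits[0].channel_label == "arm-392"

    def test_arm_loss_426_from_1358_hits(self):
        s = _spec(1358, [(932, 1000), (1358, 50)])
        assert len(nl_screen(s, self.ARM_426)) == 1

    def test_no_fragment_within_tolerance_no_hit(self):
        s = _spec(1226, [(840, 1000), (1226, 50)])
        assert nl_screen(s, self.ARM_392) == []

    def test_matches_brute_force_oracle_on_random_spectra(self):
        """nl_screen must equal an exhaustive (fragment, channel) scan."""
        channels = build_nl_library("default")
        rng = np.random.default_rng(42)
        n_checked = 0
        for k in range(1000):
            spec = random_variant_spec(rng, name=f"r{k}")
            s = make_spectrum(spec, n_decoys=int(rng.integers(0, 6)), seed=rng)
            got = {
                (h.channel_label, round(h.q1_mz, 4)) for h in nl_screen(s, channels)
            }
            expected = set()
            for ch in channels:
                for idx, (mz, _intensity) in enumerate(s.fragments):
                    if (
                        abs(s.precursor_mz - ch.loss_da - mz) <= 0.5
                        and fragment_snr(s, idx) >= 3.0
                    ):
                        expected.add((ch.label, round(s.precursor_mz, 4)))
            assert got == expected
            n_checked += 1
        assert n_checked == 1000

    def test_shrinking_tolerance_never_adds_hits(self):
        channels = build_nl_library("default")
        rng = np.random.default_rng(7)
        for k in range(50):
            s = make_spectrum(random_variant_spec(rng, f"m{k}"), 3, rng)
            wide = {h.channel_label for h in nl_screen(s, channels, mz_tol=0.8)}
            narrow = {h.channel_label for h in nl_screen(s, channels, mz_tol=0.2)}
            assert narrow <= wide


class TestFSScreen:
    def test_precursor_inside_windows_included(self):
        s = _spec(1358, [(932, 1000), (1358, 50)], rt=2.90)
        hits = fs_screen([s])
        assert len(hits) == 1
        assert hits[0].mode == "fs"

    def test_rt_beyond_window_excluded_with_boundary_flag(self, caplog):
        import logging

        logging.getLogger("amphiscan").setLevel(logging.WARNING)
        s = _spec(1506, [(1080, 1000), (1506, 50)], rt=4.38)
        with caplog.at_level("WARNING", logger="amphiscan.screening"):
            assert fs_screen([s]) == []
        assert any("outside FS window" in r.message for r in caplog.records)

    def test_mass_below_range_excluded(self):
        s = _spec(999, [(600, 1000), (999, 50)], rt=3.0)
        assert fs_screen([s]) == []

    def test_inverted_window_rejected(self):
        with pytest.raises(ValidationError):
            fs_screen([], rt_window=(4.2, 2.0))

    def test_dedup_against_nl_and_srm_hits(self):
        channels = [NLChannel(392.0, False, "arm-392")]
        s = _spec(1226, [(834, 1000), (1226, 50)], rt=3.89)
        nl_hits = nl_screen(s, channels)
        assert nl_hits
        assert fs_screen([s], exclude_hits=nl_hits) == []
        # union of modes has no duplicate Q1 per spectrum
        fs_hits = fs_screen([s], exclude_hits=nl_hits)
        q1s = [(h.spectrum_id, round(h.q1_mz)) for h in nl_hits + fs_hits]
        assert len(q1s) == len(set(q1s))


class TestSRM:
    TABLE = TransitionTable([TransitionEntry("ARC-1", 1226, 834, 3.89, False)])

    def test_matching_transition_and_rt_hits(self):
        peaks = [SrmPeak("S1", 1226, 834, 3.90, 1e5)]
        hits = srm_detect(peaks, self.TABLE)
        assert len(hits) == 1
        assert hits[0].channel_label == "ARC-1"

    def test_rt_outside_tolerance_no_hit(self):
        peaks = [SrmPeak("S1", 1226, 834, 2.00, 1e5)]
        assert srm_detect(peaks, self.TABLE, rt_tol=0.2) == []

    def test_empty_peak_list_empty_result(self):
        assert srm_detect([], self.TABLE) == []


class TestEstimateSnr:
    def test_flat_trace_snr_zero(self):
        assert estimate_snr([1.0] * 10, (4, 6)) == 0.0

    def test_hand_computed_mad_oracle(self):
        # off-peak alternates 9/11: median 10, MAD 1, noise 1.4826;
        # peak max 40 => S/N = 30 / 1.4826
        trace = [9, 11, 9, 11, 40, 35, 9, 11, 9, 11]
        assert estimate_snr(trace, (4, 6)) == pytest.approx(30.0 / 1.4826)

    def test_zero_noise_above_baseline_is_infinite(self):
        trace = [5.0] * 8 + [20.0]
        assert estimate_snr(trace, (8, 9)) == math.inf

    def test_all_zero_trace_returns_zero(self):
        assert estimate_snr([0.0] * 10, (3, 5)) == 0.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            estimate_snr([1.0] * 5, (1, 2))
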