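import numpy as np
import pytest

from beeland import segmentation
from beeland.segmentation import (ConstantRDetector, coverage_mask,
                                  detect_constant_r, extract_entries,
                                  extract_entry_segment, sweep_f)
from beeland.trajio import FS_HZ

from conftest import states_from_r


def ramp_plateau_ramp(noise_sd=0.0, rng=None):
    """r: ramp 0.5->2 (0.3 s), plateau 2.0 (0.6 s), ramp 2->3.5 (0.3 s)."""
    t = np.arange(0, 1.2, 1 / FS_HZ)
    r = np.where(t < 0.3, 0.5 + 5 * t, np.where(t < 0.9, 2.0, 2.0 + 5 * (t - 0.9)))
    return states_from_r(r, t, noise_sd=noise_sd, rng=rng), t


def two_plateau_track(noise_sd=0.05, seed=0):
    """Plateaus at 1.5 and 3.0 1/s joined by a smooth rise."""
    t = np.arange(0, 2.0, 1 / FS_HZ)
    r = np.where(t < 0.8, 1.5,
                 np.where(t < 1.1, 1.5 + 1.5 * (t - 0.8) / 0.3, 3.0))
    return states_from_r(r, t, noise_sd=noise_sd,
                         rng=np.random.default_rng(seed)), t


class TestDetectConstantR:
    def test_noiseless_plateau_detected_exactly(self):
        st, t = ramp_plateau_ramp()
        segs = detect_constant_r(st)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.r_star == pytest.approx(2.0, abs=1e-6)
        # covers (a subset of) the plateau interior
        plateau = (t >= 0.3) & (t < 0.9)
        idx = np.flatnonzero(plateau)
        assert seg.idx_start >= idx[0]
        assert seg.idx_end <= idx[-1]
        assert seg.n >= 0.5 * idx.size

    def test_segment_summary_is_the_segment_mean(self):
        st, _ = ramp_plateau_ramp(noise_sd=0.05)
        for seg in detect_constant_r(st):
            sl = slice(seg.idx_start, seg.idx_end + 1)
            assert seg.r_star == pytest.approx(np.mean(st.r[sl]), abs=1e-12)
            assert seg.y_star == pytest.approx(np.mean(st.y[sl]), abs=1e-12)

    def test_two_noisy_plateaus_recovered(self):
        st, t = two_plateau_track()
        segs = detect_constant_r(st)
        assert len(segs) >= 2
        sigma = 0.05
        lo = min(segs, key=lambda s: s.r_star)
        hi = max(segs, key=lambda s: s.r_star)
        assert abs(lo.r_star - 1.5) < 3 * sigma / np.sqrt(lo.n) + 0.02
        assert abs(hi.r_star - 3.0) < 3 * sigma / np.sqrt(hi.n) + 0.02

    def test_segments_never_overlap_and_are_ordered(self):
        st, _ = two_plateau_track(seed=3)
        segs = detect_constant_r(st)
        for a, b in zip(segs, segs[1:]):
            assert a.idx_end < b.idx_start

    @pytest.mark.parametrize("f_lo,f_hi", [(0.25, 1.5), (0.25, 2.5), (1.5, 2.5)])
    def test_coverage_monotone_in_f(self, f_lo, f_hi):
        st, _ = two_plateau_track(seed=1)
        lo = coverage_mask(st, detect_constant_r(st, f=f_lo))
        hi = coverage_mask(st, detect_constant_r(st, f=f_hi))
        assert np.all(hi[lo])          # lo coverage is a subset of hi

    def test_sweep_f_returns_all_requested(self):
        st, _ = ramp_plateau_ramp(noise_sd=0.02)
        out = sweep_f(st, fs=(0.5, 1.5, 2.5))
        assert set(out) == {0.5, 1.5, 2.5}

    def test_empty_when_no_plateau(self):
        t = np.arange(0, 0.6, 1 / FS_HZ)
        st = states_from_r(0.5 + 4.0 * t, t)
        assert detect_constant_r(st) == []

    def test_custom_detector_is_pluggable(self):
        st, _ = ramp_plateau_ramp()
        sentinel = []
        assert detect_constant_r(st, detector=lambda s: sentinel) is sentinel


class TestEntryExtraction:
    def test_increasing_entry_starts_at_r_low_crossing(self):
        # rise from 0.2: the entry must begin near the r = 0.5 crossing
        t = np.arange(0, 1.4, 1 / FS_HZ)
        r = np.where(t < 0.6, 0.2 + 3.0 * t, 2.0)
        st = states_from_r(r, t)
        segs = detect_constant_r(st)
        ents = extract_entries(st, segs)
        assert len(ents) == 1
        e = ents[0]
        t_cross = (0.5 - 0.2) / 3.0
        assert st.t[e.idx_start] == pytest.approx(t_cross, abs=4 / FS_HZ)
        assert e.direction == "increasing"
        assert e.delta_re == pytest.approx(e.r_star - e.r0, abs=1e-12)
        assert e.idx_end + 1 == e.segment.idx_start

    def test_decreasing_entry_covers_whole_fall(self):
        t = np.arange(0, 1.6, 1 / FS_HZ)
        r = np.where(t < 0.6, 4.0 - (4.0 - 2.0) * t / 0.6, 2.0)
        st = states_from_r(r, t)
        segs = detect_constant_r(st)
        ents = extract_entries(st, segs)
        assert len(ents) == 1
        e = ents[0]
        assert e.direction == "decreasing"
        assert e.delta_re < 0
        # the low-r start rule does not apply on a fall: the run begins
        # near the start of the monotonic decrease
        assert st.t[e.idx_start] < 0.1

    def test_oscillation_before_plateau_yields_none(self):
        t = np.arange(0, 1.2, 1 / FS_HZ)
        r = np.where(t < 0.5, 2.0 + 0.8 * np.sin(2 * np.pi * 15 * t), 2.0)
        st = states_from_r(r, t)
        segs = detect_constant_r(st)
        for seg in segs:
            assert extract_entry_segment(st, seg) is None

    def test_every_entry_abuts_its_plateau(self):
        st, _ = two_plateau_track(seed=7)
        segs = detect_constant_r(st)
        ents = extract_entries(st, segs)
        assert ents, "expected the 1.5 -> 3.0 transition to yield an entry"
        for e in ents:
            assert e.idx_end + 1 == e.segment.idx_start
            assert np.sign(e.delta_re) == (1 if e.direction == "increasing" else -1)


class TestEndToEndRecovery:
    def test_known_schedule_plateaus_and_entries(self):
        """Noiseless closed-loop landings over a (1, 2, 3) 1/s schedule:
        every set-point recovered within 1%, one entry per transition."""
        from beeland.kinematics import compute_states
        from beeland.synthetic import GeneratorConfig, simulate_landing
        from beeland.trajio import filter_and_align

        cfg = GeneratorConfig(schedule=(1.0, 2.0, 3.0), dwell_lo=0.5,
                              dwell_hi=0.8, y_start_lo=0.35, y_start_hi=0.45,
                              noise_sd_pos=0.0, seed=0)
        errs, n_entries = [], 0
        for seed in range(5):
            tr, gt = simulate_landing(cfg, seed)
            st = compute_states(filter_and_align([tr])[0]).final_approach()
            segs = detect_constant_r(st)
            ents = extract_entries(st, segs)
            n_entries += len(ents)
            for p in gt.plateaus:
                best = min(segs, key=lambda s: abs(s.r_star - p.r_star))
                errs.append(abs(best.r_star - p.r_star) / p.r_star)
        assert np.median(errs) < 0.01
        assert n_entries >= 2 * 5 - 1     # one per transition (first plateau opens)

    def test_noisy_boundaries_within_ten_samples(self):
        """At the default tracking noise, detected entry onsets sit within
        10 samples of the true set-point switches (median)."""
        from beeland.kinematics import compute_states
        from beeland.synthetic import GeneratorConfig, simulate_landing
        from beeland.trajio import filter_and_align

        cfg = GeneratorConfig(schedule=(1.1, 2.78), dwell_lo=0.5, dwell_hi=0.8,
                              y_start_lo=0.35, y_start_hi=0.45, seed=0)
        offs = []
        for seed in range(10):
            tr, gt = simulate_landing(cfg, seed)
            st = compute_states(filter_and_align([tr])[0]).final_approach()
            ents = extract_entries(st, detect_constant_r(st))
            t0 = st.t - st.t[0]
            for e in ents:
                p = min(gt.plateaus, key=lambda p: abs(p.r_star - e.r_star))
                offs.append(abs(t0[e.idx_start] - p.t_switch) * FS_HZ)
        assert offs
        assert np.median(offs) <= 10
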