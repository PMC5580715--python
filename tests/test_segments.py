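"""Segment calling, genetic-length filters, set classification, calibration."""

import itertools

import numpy as np
import pytest

from elscan.io import RecombinationMap
from elscan.model import InterfaceError, SiteSequence
from elscan.segments import (
    CutoffConfig,
    Segment,
    calibrate_cutoffs,
    call_segments,
    classify_sets,
    combine_archaics,
    filter_by_length,
    genetic_length,
)


def make_seq(positions):
    pos = np.asarray(positions)
    return SiteSequence(
        pos=pos,
        derived_count=np.full(len(pos), 3),
        archaic_derived=np.zeros(len(pos), dtype=bool),
        n_chrom=10,
        gpos={"uniform": pos * 1e-6},
    )


def reference_call(p, high, low):
    """Independent restatement of the calling rule: split at sites <= low,
    keep blocks with a seed >= high, span outermost seeds."""
    segs = []
    block = []
    for i, x in enumerate(list(p) + [low]):  # sentinel terminates last block
        if x <= low:
            seeds = [j for j in block if p[j] >= high]
            if seeds:
                segs.append((seeds[0], seeds[-1]))
            block = []
        else:
            block.append(i)
    return segs


class TestCallSegments:
    @pytest.mark.parametrize(
        "post,expected",
        [
            ([0.9, 0.8, 0.95], [(0, 2)]),
            ([0.9, 0.05, 0.9], [(0, 0), (2, 2)]),
            ([0.9, 0.4, 0.9], [(0, 2)]),  # 0.4 > low: no interruption
            ([0.5, 0.6, 0.5], []),  # no seed site
            ([0.05, 0.9, 0.05], [(1, 1)]),
        ],
    )
    def test_rule_examples(self, post, expected):
        seq = make_seq(np.arange(1, len(post) + 1) * 1000)
        segs = call_segments(np.array(post), seq, CutoffConfig())
        got = [(s.first_site, s.last_site) for s in segs]
        assert got == expected

    def test_all_three_site_patterns_match_reference(self):
        grid = [0.02, 0.1, 0.25, 0.7, 0.95]
        seq = make_seq([1000, 2000, 3000])
        for p in itertools.product(grid, repeat=3):
            segs = call_segments(np.array(p), seq, CutoffConfig())
            got = [(s.first_site, s.last_site) for s in segs]
            assert got == reference_call(p, 0.7, 0.1), p

    def test_coordinates_span_outer_seed_sites(self):
        seq = make_seq([100, 200, 300])
        (seg,) = call_segments(np.array([0.9, 0.4, 0.9]), seq, CutoffConfig())
        assert (seg.start, seg.end) == (99, 300)  # BED half-open around 1-based sites

    def test_misaligned_track_rejected(self):
        seq = make_seq([100, 200])
        with pytest.raises(InterfaceError):
            call_segments(np.array([0.9]), seq, CutoffConfig())

    def test_padding_invariance(self, rng):
        seq_core = make_seq(np.arange(1, 21) * 1000)
        p = rng.random(20)
        base = [
            (s.start, s.end)
            for s in call_segments(p, seq_core, CutoffConfig())
        ]
        padded_pos = np.concatenate(
            [[5, 10], np.arange(1, 21) * 1000, [50000, 60000]]
        )
        seq_pad = make_seq(padded_pos)
        p_pad = np.concatenate([[0.01, 0.05], p, [0.0, 0.02]])
        padded = [
            (s.start, s.end)
            for s in call_segments(p_pad, seq_pad, CutoffConfig())
        ]
        assert base == padded

    def test_cutoff_monotonicity(self, rng):
        for _ in range(20):
            p = rng.random(50)
            seq = make_seq(np.arange(1, 51) * 500)
            n_base = len(call_segments(p, seq, CutoffConfig(high=0.6, low=0.1)))
            n_higher_seed = len(call_segments(p, seq, CutoffConfig(high=0.8, low=0.1)))
            assert n_higher_seed <= n_base
            n_higher_low = len(call_segments(p, seq, CutoffConfig(high=0.6, low=0.3)))
            assert n_higher_low >= n_base

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            CutoffConfig(high=0.1, low=0.7)


class TestGeneticLength:
    def test_constant_rate_map(self):
        m = RecombinationMap.uniform(1.0, 1_000_000)
        seg = Segment(chrom="1", start=100_000, end=150_000, seed_sites=1, max_posterior=0.9)
        assert genetic_length(seg, m) == pytest.approx(0.05)

    def test_zero_span_is_zero(self):
        m = RecombinationMap.uniform(1.0, 1_000_000)
        assert m.distance(5000, 5000) == 0.0

    def test_piecewise_integral(self):
        # 0.5 cM/Mb over the first 10 kb, 2 cM/Mb over the next 10 kb
        m = RecombinationMap(
            pos=[0, 10_000, 20_000],
            cum_cm=[0.0, 0.005, 0.045],
            name="piecewise",
        )
        seg = Segment(chrom="1", start=0, end=20_000, seed_sites=1, max_posterior=0.9)
        assert genetic_length(seg, m) == pytest.approx(0.005 + 0.04)

    def test_additive_over_bisection(self):
        m = RecombinationMap(
            pos=[0, 7_000, 13_000, 30_000],
            cum_cm=[0.0, 0.01, 0.02, 0.1],
            name="m",
        )
        whole = m.distance(1_000, 25_000)
        assert whole == pytest.approx(m.distance(1_000, 9_000) + m.distance(9_000, 25_000))

    def test_outside_coverage_is_unmeasurable(self):
        m = RecombinationMap(pos=[10_000, 20_000], cum_cm=[0.0, 0.01], name="m")
        seg = Segment(chrom="1", start=0, end=15_000, seed_sites=1, max_posterior=0.9)
        assert genetic_length(seg, m) is None


def _seg(start, end, **kw):
    kw.setdefault("chrom", "1")
    kw.setdefault("seed_sites", 1)
    kw.setdefault("max_posterior", 0.9)
    return Segment(start=start, end=end, **kw)


class TestClassifySets:
    def setup_method(self):
        self.maps = {
            "a": RecombinationMap.uniform(1.0, 1_000_000, name="a"),
            "b": RecombinationMap.uniform(1.0, 1_000_000, name="b"),
        }

    def test_identical_passing_calls_are_core(self):
        calls = {
            "a": [_seg(100_000, 140_000)],
            "b": [_seg(100_000, 140_000)],
        }
        core, extended = classify_sets(calls, self.maps)
        assert len(core) == 1 and core[0].set_label == "core"
        assert len(extended) == 2
        assert core[0].glen_per_map == pytest.approx({"a": 0.04, "b": 0.04})

    def test_single_map_pass_is_extended_only(self):
        # 40 kb under map a; map b has a cold spot making it 4x shorter
        cold = RecombinationMap(
            pos=[0, 100_000, 140_000, 1_000_000],
            cum_cm=[0.0, 0.1, 0.11, 0.97],
            name="b",
        )
        maps = {"a": self.maps["a"], "b": cold}
        calls = {"a": [_seg(100_000, 140_000)], "b": [_seg(100_000, 140_000)]}
        core, extended = classify_sets(calls, maps)
        assert core == []
        labels = {s.set_label for s in extended}
        assert labels == {"extended"}
        assert len(extended) == 1  # only the map-a call passes

    def test_disjoint_calls_retained_per_map(self):
        calls = {
            "a": [_seg(100_000, 140_000)],
            "b": [_seg(500_000, 540_000)],
        }
        core, extended = classify_sets(calls, self.maps)
        assert core == []
        assert {(s.start, s.end) for s in extended} == {
            (100_000, 140_000), (500_000, 540_000)
        }

    def test_core_uses_overlap_interval(self):
        calls = {
            "a": [_seg(100_000, 160_000)],
            "b": [_seg(120_000, 200_000)],
        }
        core, extended = classify_sets(calls, self.maps)
        assert len(core) == 1
        assert (core[0].start, core[0].end) == (120_000, 160_000)

    def test_every_core_overlaps_an_extended_segment(self):
        calls = {
            "a": [_seg(100_000, 160_000), _seg(400_000, 430_000)],
            "b": [_seg(110_000, 170_000)],
        }
        core, extended = classify_sets(calls, self.maps)
        for c in core:
            assert any(c.overlaps(e) for e in extended)

    def test_x_chromosome_threshold(self):
        calls = {"a": [_seg(100_000, 130_000)], "b": [_seg(100_000, 130_000)]}
        core_auto, _ = classify_sets(calls, self.maps, chrom_is_X=False)
        calls = {"a": [_seg(100_000, 130_000)], "b": [_seg(100_000, 130_000)]}
        core_x, _ = classify_sets(calls, self.maps, chrom_is_X=True)
        assert len(core_auto) == 1  # 0.03 cM passes 0.025
        assert core_x == []  # but not the stricter 0.035 X cutoff


class TestCombineArchaics:
    def test_intersection_of_overlapping_calls(self):
        calls = {
            "nea": [_seg(100, 220)],
            "den": [_seg(180, 300)],
        }
        out = combine_archaics(calls, require_all=True)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (180, 220)
        assert out[0].archaic_support == ("nea", "den")

    def test_unsupported_call_dropped_when_all_required(self):
        calls = {"nea": [_seg(100, 200)], "den": [_seg(5000, 6000)]}
        assert combine_archaics(calls, require_all=True) == []

    def test_single_archaic_mode_keeps_all(self):
        calls = {"nea": [_seg(100, 200), _seg(300, 400)]}
        assert len(combine_archaics(calls, require_all=False)) == 2


class TestCalibrateCutoffs:
    def test_perfect_posteriors_tie_break(self):
        p = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        t = (p > 0.5).astype(float)
        cfg = calibrate_cutoffs([(p, t)])
        assert (cfg.high, cfg.low) == (0.95, 0.90)

    def test_all_zero_is_perfect(self):
        p = np.zeros(10)
        t = np.zeros(10)
        cfg = calibrate_cutoffs([(p, t)])
        assert (cfg.high, cfg.low) == (0.95, 0.90)

    def test_noisy_posteriors_select_separating_cutoffs(self, rng):
        truth = np.zeros(200)
        truth[80:120] = 1.0
        post = np.where(truth == 1, 0.75, 0.3) + rng.normal(0, 0.02, size=200)
        post = np.clip(post, 0, 1)
        cfg = calibrate_cutoffs([(post, truth)])
        # any high cutoff separating 0.3-noise from 0.75-signal is optimal;
        # the conservative tie-break picks the largest one below the signal
        assert 0.4 <= cfg.high <= 0.75
        assert cfg.low < cfg.high

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_cutoffs([])


def test_filter_by_length_modes():
    s1 = _seg(0, 30_000, glen_per_map={"a": 0.03, "b": 0.02})
    s2 = _seg(0, 30_000, glen_per_map={"a": 0.03, "b": 0.028})
    assert filter_by_length([s1, s2], 0.025, how="any") == [s1, s2]
    assert filter_by_length([s1, s2], 0.025, how="all") == [s2]
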