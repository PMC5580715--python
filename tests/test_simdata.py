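"""Simulators: exact-model generator, coalescent scenarios, labels, forward engine."""

import numpy as np
import pytest

from elscan.model import ModelParams, transition_matrix
from elscan.simdata import (
    DemographyConfig,
    SweepConfig,
    conditional_fixation_time,
    evaluate_detection,
    matched_age_selection,
    measured_emissions,
    simulate_from_hmm,
    simulate_neutral,
    simulate_sweep,
)

PARAMS = ModelParams(
    l_I=0.012, l_E=0.0016, l_ELS=0.05, p=0.05,
    eps_I=0.02, theta_E_fix=0.6, theta_I=np.linspace(0.05, 0.95, 20),
)


@pytest.fixture(scope="module")
def big_hmm_sim():
    return simulate_from_hmm(PARAMS, L=400_000, seed=7)


class TestSimulateFromHmm:
    def test_p_zero_never_visits_els(self):
        _, states = simulate_from_hmm(PARAMS.copy(p=0.0), L=20_000, seed=1)
        assert not np.any(states == 2)

    def test_reproducible_by_seed(self):
        a, sa = simulate_from_hmm(PARAMS, L=5_000, seed=42)
        b, sb = simulate_from_hmm(PARAMS, L=5_000, seed=42)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.archaic_derived, b.archaic_derived)
        assert np.array_equal(sa, sb)

    def test_empirical_transitions_match_matrix(self, big_hmm_sim):
        seq, states = big_hmm_sim
        d = np.diff(seq.gpos["uniform"])
        # compare realized transition frequencies out of state I with the
        # mean predicted probabilities (distances vary per step)
        from_I = states[:-1] == 0
        n = from_I.sum()
        pred = np.array([transition_matrix(PARAMS, float(x))[0] for x in d[from_I][:2000]])
        pred_mean = np.array(
            [np.mean([transition_matrix(PARAMS, float(x))[0, k] for x in d[from_I]])
             for k in range(3)]
        )
        for k in range(3):
            obs = np.mean(states[1:][from_I] == k)
            se = np.sqrt(pred_mean[k] * (1 - pred_mean[k]) / n)
            assert abs(obs - pred_mean[k]) < 3 * se + 1e-4

    def test_mean_external_run_length_matches_l_e(self, big_hmm_sim):
        seq, states = big_hmm_sim
        g = seq.gpos["uniform"]
        runs = []
        start = None
        for i, s in enumerate(states):
            if s == 1 and start is None:
                start = i
            elif s != 1 and start is not None:
                runs.append(g[i - 1] - g[start])
                start = None
        # the realized genetic run length omits the exponential tails beyond
        # the first/last site of the run; half an inter-site spacing on each
        # side compensates
        spacing = np.mean(np.diff(g))
        mean_run = np.mean(runs) + spacing
        assert mean_run == pytest.approx(PARAMS.l_E, rel=0.05)

    def test_emission_frequencies_match_parameters(self, big_hmm_sim):
        seq, states = big_hmm_sim
        cls = seq.freq_classes(20)
        ext = states > 0
        seg = cls < 20
        obs_eps_e = seq.archaic_derived[ext & seg].mean()
        assert obs_eps_e == pytest.approx(0.01, abs=0.005)
        obs_theta_fix = seq.archaic_derived[ext & ~seg].mean()
        assert obs_theta_fix == pytest.approx(0.6, abs=0.02)


class TestNeutralCoalescent:
    def test_trio_topology_closed_form(self):
        # 2 modern chromosomes + archaic in an effectively panmictic
        # population: the archaic is the outgroup in 1/3 of the genome
        demog = DemographyConfig(
            n_modern=2,
            ne_modern=10_000, ne_modern_deep=10_000, ne_archaic=10_000,
            ne_ancestral=10_000,
            t_split_kya=0.03, t_archaic_sample_kya=0.001, t_deep_kya=0.002,
        )
        regions = simulate_neutral(demog, region_bp=300_000, n_reps=12, seed=5)
        frac = np.mean([r.external_fraction for r in regions])
        # ~1800 coarsely correlated tracts pooled: generous Monte-Carlo band
        assert frac == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_reproducible_and_labels_consistent_with_trees(self):
        demog = DemographyConfig(n_modern=30)
        r1 = simulate_neutral(demog, region_bp=200_000, n_reps=1, seed=8, keep_ts=True)[0]
        r2 = simulate_neutral(demog, region_bp=200_000, n_reps=1, seed=8)[0]
        assert np.array_equal(r1.seq.pos, r2.seq.pos)
        assert np.array_equal(r1.external, r2.external)
        # spot-check labels against direct tree queries
        humans = list(range(demog.n_modern))
        for i in np.linspace(0, len(r1.seq) - 1, 25, dtype=int):
            pos0 = int(r1.seq.pos[i]) - 1
            tree = r1.ts.at(pos0)
            m = tree.mrca(*humans)
            assert r1.external[i] == (not tree.is_descendant(demog.n_modern, m))

    def test_stem_sites_present_and_fixed_derived(self):
        region = simulate_neutral(region_bp=200_000, n_reps=1, seed=3)[0]
        cls = region.seq.freq_classes(20)
        fixed = cls == 20
        assert fixed.sum() > 100  # shared-stem substitutions dominate
        # fixed sites inside internal regions carry the derived archaic allele
        m = measured_emissions([region])
        assert m["eps_I"] < 0.05
        assert 0.4 < m["theta_E_fix"] < 0.95


class TestSweep:
    def test_s_zero_reduces_to_neutral(self):
        demog = DemographyConfig(n_modern=40)
        sw = simulate_sweep(
            demog, SweepConfig(s=0.0, age_kya=400), region_bp=200_000,
            n_reps=3, seed=21,
        )
        assert all(r.fixed is False for r in sw)
        assert all(r.selected_pos == 100_000 for r in sw)
        # distributionally neutral: external fraction in the neutral range
        fr = np.mean([r.external_fraction for r in sw])
        assert 0.0 <= fr < 0.5

    def test_focal_site_external_when_conditioned_fixed(self):
        sw = simulate_sweep(
            sweep=SweepConfig(s=0.01, age_kya=500), n_reps=3, seed=33,
            region_bp=600_000,
        )
        hits = [r.focal_tract_cm() for r in sw]
        assert sum(h is not None for h in hits) >= 2

    def test_strong_selection_produces_long_regions(self):
        sw = simulate_sweep(
            sweep=SweepConfig(s=0.05, age_kya=600), n_reps=4, seed=13,
            region_bp=1_000_000,
        )
        lens = [r.focal_tract_cm() or 0 for r in sw]
        assert max(lens) > 0.1

    def test_conditioning_any_records_fate(self):
        demog = DemographyConfig(n_modern=20)
        sw = simulate_sweep(
            demog, SweepConfig(s=0.001, age_kya=300, conditioning="any"),
            region_bp=100_000, n_reps=6, seed=2,
        )
        fates = [r.fixed for r in sw]
        assert all(f in (True, False) for f in fates)
        assert any(f is False for f in fates)  # weak alleles are usually lost

    def test_fixation_time_decreases_with_selection(self):
        ne = 20_000
        assert conditional_fixation_time(0.05, ne) < conditional_fixation_time(0.005, ne)

    def test_matched_age_selection_matches_duration(self):
        demog = DemographyConfig()
        s = matched_age_selection(600, demog)
        dur = conditional_fixation_time(s, demog.ne_modern_deep)
        assert dur == pytest.approx(demog.gens(600) - demog.t_deep_gens - 1, rel=0.01)


class TestEvaluateDetection:
    def test_perfect_calls(self):
        region = simulate_sweep(
            sweep=SweepConfig(s=0.05, age_kya=500), n_reps=1, seed=3,
            region_bp=400_000,
        )[0]
        from elscan.segments import Segment

        tract = [t for t in region.tracts if t[0] <= region.selected_pos < t[1]][0]
        call = Segment(chrom="1", start=int(tract[0]), end=int(tract[1]),
                       seed_sites=5, max_posterior=1.0)
        summary = evaluate_detection([region], [[call]])
        assert summary.tp_rate == 1.0
        assert summary.fp_rate == 0.0

    def test_miss_and_false_region_accounting(self):
        region = simulate_sweep(
            sweep=SweepConfig(s=0.05, age_kya=500), n_reps=1, seed=3,
            region_bp=400_000,
        )[0]
        from elscan.segments import Segment

        off_target = Segment(chrom="1", start=10, end=50, seed_sites=1, max_posterior=0.9)
        summary = evaluate_detection([region], [[off_target]])
        assert summary.n_detected == 0
        assert summary.n_false_regions == 1


class TestForwardEngine:
    def test_neutral_branch_diversity_matches_coalescent(self):
        from elscan.wrightfisher import forward_neutral_diversity_check

        n = 40
        vals = [
            forward_neutral_diversity_check(
                n_diploids=n, region_bp=40_000, n_gens=12 * n,
                recomb_per_bp=2e-6, seed=100 + i,
            )
            for i in range(12)
        ]
        assert np.mean(vals) == pytest.approx(4 * n, rel=0.05)

    def test_bgs_proxy_runs_and_labels(self):
        from elscan.simdata import simulate_background_selection_proxy

        regions = simulate_background_selection_proxy(
            del_rate=2e-8, region_bp=150_000, n_reps=1, seed=5, rescale=100.0,
        )
        r = regions[0]
        assert len(r.seq) > 50
        assert r.external.shape == (len(r.seq),)
        assert 0 <= r.external_fraction <= 1

    def test_bgs_regions_shorter_than_strong_sweep_regions(self):
        from elscan.simdata import simulate_background_selection_proxy

        regions = simulate_background_selection_proxy(
            del_rate=2e-8, region_bp=150_000, n_reps=2, seed=11, rescale=100.0,
        )
        bgs_max = max(
            (x for r in regions for x in r.external_lengths_cm()), default=0.0
        )
        sweep = simulate_sweep(
            sweep=SweepConfig(s=0.05, age_kya=600), n_reps=2, seed=13,
            region_bp=1_000_000,
        )
        sweep_max = max(r.focal_tract_cm() or 0 for r in sweep)
        assert bgs_max < sweep_max
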