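"""Occupancy, Monte Carlo bias test vs exact enumeration, hotspots, motif."""

import numpy as np
import pytest
from scipy import stats as sps

import tol2sites as t


def ev(pos, orient="+", exp="exp1", eid=None, tsd=None, plasmid=None):
    seq = plasmid.fetch(pos, 8) if plasmid is not None else (tsd or "ACGTACGT")
    return t.InsertionEvent(eid or f"e{pos}_{orient}_{exp}", pos, orient, seq, 8, True, exp)


class TestFeatureOccupancy:
    def test_no_events_all_zero(self, tiled_plasmid):
        occ = t.feature_occupancy([], tiled_plasmid)
        assert occ.counts.sum() == 0 and occ.names == [f.name for f in tiled_plasmid.features]

    def test_counts_match_hand_tally(self):
        p = t.TargetPlasmid(
            "p", "A" * 300,
            [t.Feature("a", 0, 100), t.Feature("b", 100, 200), t.Feature("c", 200, 300)],
        )
        events = [ev(x, plasmid=p) for x in [5, 50, 99, 100, 150, 250, 250, 299, 0, 199]]
        occ = t.feature_occupancy(events, p)
        assert dict(zip(occ.names, occ.counts)) == {"a": 4, "b": 3, "c": 3}

    def test_boundary_event_goes_to_following_feature(self):
        p = t.TargetPlasmid("p", "A" * 200, [t.Feature("a", 0, 100), t.Feature("b", 100, 200)])
        occ = t.feature_occupancy([ev(100, plasmid=p)], p)
        assert dict(zip(occ.names, occ.counts)) == {"a": 0, "b": 1}

    def test_uncovered_length_becomes_unannotated_feature(self):
        p = t.TargetPlasmid("p", "A" * 200, [t.Feature("a", 0, 50)])
        occ = t.feature_occupancy([ev(120, plasmid=p)], p)
        assert occ.names == ["a", "unannotated"]
        assert list(occ.lengths) == [50, 150] and list(occ.counts) == [0, 1]

    def test_overlapping_features_rejected(self):
        p = t.TargetPlasmid("p", "A" * 200, [t.Feature("a", 0, 120), t.Feature("b", 100, 200)])
        with pytest.raises(t.AmbiguousAnnotationError):
            t.feature_occupancy([], p)


class TestMonteCarloBiasTest:
    def test_single_feature_p_greater_is_one(self):
        occ = t.OccupancyTable(["all"], [100], [20])
        mc = t.monte_carlo_bias_test(occ, n_sims=500, seed=0)
        assert mc.p_for("all") == (1.0, 1.0)

    def test_agrees_with_exact_binomial_tail(self):
        occ = t.OccupancyTable(["a", "b"], [100, 100], [5, 0])
        mc = t.monte_carlo_bias_test(occ, n_sims=10_000, seed=3)
        p_hat = mc.p_for("a")[0]
        exact = 1 / 32
        assert abs(p_hat - exact) <= 3 * np.sqrt(exact * (1 - exact) / 10_000)

    def test_add_one_correction_keeps_p_positive(self):
        occ = t.OccupancyTable(["a", "b", "c", "d"], [100] * 4, [75, 0, 0, 0])
        mc = t.monte_carlo_bias_test(occ, n_sims=10_000, seed=1)
        assert 0 < mc.p_for("a")[0] < 1e-4
        assert np.all(mc.p_greater > 0) and np.all(mc.p_less > 0)

    def test_reproducible_from_seed(self):
        occ = t.OccupancyTable(["a", "b"], [30, 70], [4, 6])
        a = t.monte_carlo_bias_test(occ, n_sims=2000, seed=5)
        b = t.monte_carlo_bias_test(occ, n_sims=2000, seed=5)
        assert np.array_equal(a.p_greater, b.p_greater) and np.array_equal(a.p_less, b.p_less)

    def test_empty_occupancy_rejected(self):
        with pytest.raises(t.EmptyInputError):
            t.monte_carlo_bias_test(t.OccupancyTable(["a"], [10], [0]), seed=0)

    @pytest.mark.parametrize(
        "lengths,counts,focal",
        [
            ([50, 50], [5, 0], "f0"),
            ([10, 30, 60], [2, 3, 5], "f2"),
            ([25, 25, 25, 25], [0, 4, 4, 4], "f1"),
            ([100, 50, 30, 20], [1, 1, 5, 5], "f3"),
        ],
    )
    def test_monte_carlo_matches_enumeration_oracle(self, lengths, counts, focal):
        """On every enumerable instance the empirical tail agrees with the
        exact multinomial tail within three Monte Carlo standard errors."""
        names = [f"f{i}" for i in range(len(lengths))]
        occ = t.OccupancyTable(names, lengths, counts)
        exact = t.exact_multinomial_tail(occ, focal)
        n_sims = 10_000
        mc = t.monte_carlo_bias_test(occ, n_sims=n_sims, seed=7)
        se = np.sqrt(exact * (1 - exact) / n_sims)
        assert abs(mc.p_for(focal)[0] - exact) <= 3 * se + 2 / n_sims

    def test_null_counts_follow_exact_multinomial_marginal(self, tiled_plasmid):
        """Under the uniform generator the focal-feature count over many
        replicate experiments matches the exact Binomial(75, 1/4) marginal
        (chi-square goodness of fit): the null the test simulates is the
        null the generator produces."""
        rng = np.random.default_rng(31)
        focal_counts = []
        for _ in range(300):
            events = t.simulate_insertions(
                tiled_plasmid, 75, t.BiasModel(beta_at=0.0), seed=int(rng.integers(2**31 - 1))
            )
            occ = t.feature_occupancy(events, tiled_plasmid)
            focal_counts.append(occ.counts[0])
        edges = [0, 13, 15, 17, 19, 21, 23, 25, 76]
        obs, _ = np.histogram(focal_counts, bins=edges)
        probs = np.diff([sps.binom.cdf(e - 0.5, 75, 0.25) for e in edges])
        res = sps.chisquare(obs, f_exp=300 * probs / probs.sum())
        assert res.pvalue > 0.001


class TestExactMultinomialTail:
    def test_two_equal_features_five_zero(self):
        occ = t.OccupancyTable(["a", "b"], [100, 100], [5, 0])
        assert t.exact_multinomial_tail(occ, "a") == pytest.approx(2**-5)

    def test_observed_zero_gives_probability_one(self):
        occ = t.OccupancyTable(["a", "b"], [100, 100], [0, 5])
        assert t.exact_multinomial_tail(occ, "a") == pytest.approx(1.0)

    def test_three_features_all_counts_in_first(self):
        occ = t.OccupancyTable(["a", "b", "c"], [50, 30, 20], [4, 0, 0])
        assert t.exact_multinomial_tail(occ, "a") == pytest.approx(0.5**4)

    def test_matches_closed_form_binomial_marginal(self):
        occ = t.OccupancyTable(["a", "b", "c"], [20, 30, 50], [3, 4, 3])
        for name, p in zip(occ.names, occ.probabilities):
            obs = occ.counts[occ.names.index(name)]
            assert t.exact_multinomial_tail(occ, name) == pytest.approx(
                sps.binom.sf(obs - 1, occ.n_total, p)
            )

    def test_large_instance_rejected(self):
        occ = t.OccupancyTable(["a", "b"], [10, 10], [13, 0])
        with pytest.raises(t.UnsupportedSizeError):
            t.exact_multinomial_tail(occ, "a")


class TestCallHotspots:
    def test_multi_experiment_rule(self):
        events = [ev(100, "+", "exp1"), ev(100, "-", "exp2")]
        (h,) = t.call_hotspots(events)
        assert (h.position, h.rule_fired) == (100, "multi-experiment")

    def test_same_experiment_same_orientation_is_not_a_hotspot(self):
        events = [ev(200, "+", "exp1", eid="a"), ev(200, "+", "exp1", eid="b")]
        assert t.call_hotspots(events) == []

    def test_bidirectional_within_experiment_rule(self):
        events = [ev(300, "+", "exp1", eid="a"), ev(300, "-", "exp1", eid="b")]
        (h,) = t.call_hotspots(events)
        assert h.rule_fired == "bidirectional-within-experiment"

    def test_invariant_to_order_and_experiment_relabeling(self):
        events = [
            ev(10, "+", "exp1", eid="a"), ev(10, "-", "exp2", eid="b"),
            ev(50, "+", "exp1", eid="c"), ev(50, "-", "exp1", eid="d"),
            ev(90, "+", "exp3", eid="e"),
        ]
        base = t.call_hotspots(events)
        shuffled = t.call_hotspots(events[::-1])
        assert [(h.position, h.rule_fired) for h in base] == [
            (h.position, h.rule_fired) for h in shuffled
        ]
        relabel = {"exp1": "expB", "exp2": "expC", "exp3": "expA"}
        renamed = t.call_hotspots(
            [t.InsertionEvent(e.event_id, e.position, e.orientation, e.tsd_seq,
                              e.tsd_len, e.canonical, relabel[e.experiment]) for e in events]
        )
        assert [(h.position, h.rule_fired) for h in renamed] == [
            (h.position, h.rule_fired) for h in base
        ]

    def test_tolerance_groups_nearby_positions(self):
        events = [ev(100, "+", "exp1"), ev(102, "-", "exp2")]
        assert t.call_hotspots(events, tolerance=0) == []
        (h,) = t.call_hotspots(events, tolerance=2)
        assert h.position == 100 and h.rule_fired == "multi-experiment"

    def test_empty_input_empty_output(self):
        assert t.call_hotspots([]) == []


class TestMotif:
    def planted_plasmid(self, word="TAACTTATAAGTAA", n_sites=20, spacing=40):
        rng = np.random.default_rng(13)
        seq = list("".join(rng.choice(list("ACGT"), size=n_sites * spacing)))
        positions = []
        for i in range(n_sites):
            start = i * spacing
            seq[start : start + len(word)] = word
            positions.append(start + 3)  # insertion point: first base of the 8-bp word
        return t.TargetPlasmid("planted", "".join(seq)), positions

    def test_planted_sites_recover_their_consensus(self):
        plasmid, positions = self.planted_plasmid()
        events = [ev(p, plasmid=plasmid, eid=f"e{p}") for p in positions]
        motif = t.build_motif(events, plasmid)
        assert motif.consensus == "TAACTTATAAGTAA"
        assert t.iupac_compatible(motif.consensus, t.REFERENCE_CONSENSUS)

    def test_minus_strand_sites_are_reverse_complemented(self):
        plasmid, positions = self.planted_plasmid()
        # plant the revcomp motif so '-' extraction reads the forward word
        events = [
            t.InsertionEvent(f"e{p}", p, "-", plasmid.fetch(p, 8), 8, True) for p in positions
        ]
        motif = t.build_motif(events, plasmid)
        assert motif.consensus == t.revcomp("TAACTTATAAGTAA")

    def test_uniform_columns_give_N(self, rng):
        plasmid = t.TargetPlasmid("u", "".join(rng.choice(list("ACGT"), size=4000)))
        events = [ev(p, plasmid=plasmid, eid=f"e{p}") for p in range(10, 3900, 13)]
        motif = t.build_motif(events, plasmid)
        assert set(motif.consensus) == {"N"}

    def test_column_counts_conserve_site_number(self, study_plasmid):
        events = t.simulate_insertions(study_plasmid, 120, t.BiasModel(tsd_fidelity=1.0), seed=3)
        motif = t.build_motif(events, study_plasmid)
        assert motif.n_sites == 120 and motif.n_skipped == 0
        assert np.all(motif.counts.sum(axis=0) == 120)

    def test_noncanonical_events_skipped_with_count(self, study_plasmid):
        events = t.simulate_insertions(study_plasmid, 100, t.BiasModel(tsd_fidelity=0.0), seed=4)
        motif = t.build_motif(events, study_plasmid)
        assert motif.n_sites == 0 and motif.n_skipped == 100

    def test_consensus_invariant_to_event_order(self, study_plasmid):
        events = t.simulate_insertions(study_plasmid, 60, t.BiasModel(tsd_fidelity=1.0), seed=5)
        assert (
            t.build_motif(events, study_plasmid).consensus
            == t.build_motif(events[::-1], study_plasmid).consensus
        )


class TestAtEnrichment:
    def test_all_at_plasmid_is_saturated(self):
        p = t.TargetPlasmid("at", "AT" * 100)
        site, background, _ = t.at_enrichment([ev(10, plasmid=p)], p, window=11)
        assert site == 1.0 and background == 1.0

    def test_constructed_feature_reports_its_at_content(self, study_plasmid):
        _, _, per_feature = t.at_enrichment([], study_plasmid)
        assert per_feature["sv40_polyA"] == pytest.approx(0.64, abs=0.005)

    def test_biased_events_sit_in_at_rich_context(self, study_plasmid):
        events = t.simulate_insertions(study_plasmid, 2000, t.BiasModel(beta_at=8.0), seed=6)
        site, background, _ = t.at_enrichment(events, study_plasmid, window=51)
        assert site > background
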