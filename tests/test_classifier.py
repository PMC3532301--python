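"""Nearest-neighbour assignment, LOOCV, length sweep, distance bins."""
import math
import random
from collections import Counter

import pytest

from rxndiff import worked_examples as wx
from rxndiff.classifier import (
    CVReport,
    PredictionRecord,
    TrainingEntry,
    assign_ec,
    distance_binned_accuracy,
    length_sweep,
    loocv,
    prepare_training,
)
from rxndiff.dataset import ECLabel, Reaction
from rxndiff.errors import ClassifierError, ZeroFingerprintError
from rxndiff.fingerprint import (
    ReactionDifferenceFingerprint,
    euclidean_distance,
    reaction_difference_fingerprint,
)


def rfp(entries, max_len=3, directed=False):
    return ReactionDifferenceFingerprint(entries, max_len, directed)


def entry(rid, entries, ec):
    return TrainingEntry(rid, rfp(entries), ECLabel.parse(ec))


class TestAssign:
    def test_identical_training_reaction_wins_at_distance_zero(self):
        training = [entry("T1", {"C-N": 1}, "2.1.1"),
                    entry("T2", {"C-O": 4}, "3.1.1")]
        result = assign_ec(rfp({"C-N": 1}), training)
        assert str(result.ec) == "2.1.1"
        assert result.min_distance == 0.0
        assert result.supporting_ids == ("T1",)
        assert not result.tie_broken

    def test_methyltransferase_query_matches_published_neighbour(
            self, worked_compounds):
        """The uncharacterised tryptophan N-methylation is assigned EC 2.1.1
        from the serotonin N-methylation, the published nearest neighbour."""
        decoys = [wx.R00005]  # hydrolase, far away
        training = prepare_training(
            [wx.R02910] + decoys, worked_compounds, 3, directed=True)
        result = assign_ec(wx.R00683, training, compounds=worked_compounds,
                           max_len=3, directed=True)
        assert str(result.ec) == "2.1.1"
        assert result.supporting_ids == ("R02910",)
        assert result.min_distance == pytest.approx(2.0)

    def test_reverse_deduplicated_counting_halves_that_distance(
            self, worked_compounds):
        a = reaction_difference_fingerprint(wx.R00683, worked_compounds, 3)
        b = reaction_difference_fingerprint(wx.R02910, worked_compounds, 3)
        assert euclidean_distance(a, b) == pytest.approx(1.0)

    def test_majority_rule_among_equidistant_supporters(self):
        training = [entry("T1", {"A": 1}, "2.1.1"),
                    entry("T2", {"B": 1}, "2.1.1"),
                    entry("T3", {"C": 1}, "3.1.1")]
        result = assign_ec(rfp({"D": 1}), training)  # all at sqrt(2)
        assert str(result.ec) == "2.1.1"
        assert set(result.supporting_ids) == {"T1", "T2", "T3"}
        assert result.tie_broken

    def test_residual_frequency_tie_breaks_lexicographically(self):
        training = [entry("T1", {"A": 1}, "3.5.1"),
                    entry("T2", {"B": 1}, "2.7.1")]
        result = assign_ec(rfp({"D": 1}), training)
        assert str(result.ec) == "2.7.1"
        assert result.tie_broken

    def test_training_order_never_matters(self):
        rng = random.Random(7)
        training = [entry(f"T{i}", {k: 1 + (i % 3)}, ec)
                    for i, (k, ec) in enumerate(
                        [("A", "2.1.1"), ("B", "3.1.1"), ("C", "2.1.1"),
                         ("D", "4.2.1"), ("E", "3.1.1")])]
        query = rfp({"A": 2, "B": 1})
        baseline = assign_ec(query, training)
        for _ in range(10):
            rng.shuffle(training)
            again = assign_ec(query, training)
            assert again.ec == baseline.ec
            assert again.min_distance == baseline.min_distance
            assert set(again.supporting_ids) == set(baseline.supporting_ids)

    def test_farther_training_reaction_never_changes_assignment(self):
        training = [entry("T1", {"A": 1}, "2.1.1")]
        query = rfp({"A": 2})
        before = assign_ec(query, training)
        training.append(entry("T2", {"A": 50}, "6.3.1"))
        after = assign_ec(query, training)
        assert (before.ec, before.min_distance, before.supporting_ids) == \
               (after.ec, after.min_distance, after.supporting_ids)

    def test_zero_query_fingerprint_is_refused(self):
        training = [entry("T1", {"A": 1}, "2.1.1")]
        with pytest.raises(ZeroFingerprintError):
            assign_ec(rfp({}), training)

    def test_empty_training_set_is_an_error(self):
        with pytest.raises(ClassifierError):
            assign_ec(rfp({"A": 1}), [])

    def test_matches_exhaustive_brute_force_scan(self, synthetic_set,
                                                 synthetic_graphs):
        """Optimised assignment agrees with an independent dense scan."""
        entries = prepare_training(synthetic_set.reactions, synthetic_graphs, 3)
        for probe in entries[::3]:
            others = [e for e in entries if e.reaction_id != probe.reaction_id]
            got = assign_ec(probe.rfp, others)
            # oracle: float distances, sort, majority count, lexicographic min
            dists = [(euclidean_distance(probe.rfp, e.rfp), e) for e in others]
            dmin = min(d for d, _ in dists)
            support = [e for d, e in dists if abs(d - dmin) < 1e-12]
            freq = Counter(str(e.ec) for e in support)
            best = max(freq.values())
            expect = min(ec for ec, n in freq.items() if n == best)
            assert str(got.ec) == expect
            assert got.min_distance == pytest.approx(dmin)

    def test_four_level_training_ecs_are_truncated(self, worked_compounds):
        rxn = Reaction("T", wx.R02910.reactants, wx.R02910.products,
                       ECLabel.parse("2.1.1.87"))
        entries = prepare_training([rxn], worked_compounds, 3)
        assert str(entries[0].ec) == "2.1.1"

    def test_shallow_training_ec_is_rejected(self, worked_compounds):
        rxn = Reaction("T", wx.R02910.reactants, wx.R02910.products,
                       ECLabel.parse("2.1"))
        with pytest.raises(ClassifierError):
            prepare_training([rxn], worked_compounds, 3)


def _two_template_quartet():
    """Two methylation-template and two hydrolysis-template reactions whose
    template partners are mutual nearest neighbours (verified by direct
    distance computation in the test)."""
    return [
        TrainingEntry("M1", rfp({"C-O": 1, "C-N": -1, "C-N-C": -1,
                                 "C-N-C-C": -1}), ECLabel.parse("2.1.1")),
        TrainingEntry("M2", rfp({"C-O": 1, "C-N": -1, "C-N-C": -1,
                                 "C-N-C-c": -1}), ECLabel.parse("2.1.1")),
        TrainingEntry("H1", rfp({"C-O-C": 1, "C-C-O-C": 1, "C-O-C=O": 1}),
                      ECLabel.parse("3.1.1")),
        TrainingEntry("H2", rfp({"C-O-C": 1, "C-C-O-C": 2, "C-O-C=O": 1}),
                      ECLabel.parse("3.1.1")),
    ]


class TestLoocv:
    def test_two_well_separated_templates_score_perfectly(self):
        entries = _two_template_quartet()
        # verify the premise by direct distance computation
        for e in entries:
            same = [euclidean_distance(e.rfp, o.rfp) for o in entries
                    if o is not e and o.ec == e.ec]
            diff = [euclidean_distance(e.rfp, o.rfp) for o in entries
                    if o.ec != e.ec]
            assert min(same) < min(diff)
        report = _loocv_over_entries(entries)
        assert report.accuracy(1) == report.accuracy(2) == report.accuracy(3) == 1.0

    def test_one_misassigned_by_construction_gives_two_thirds(self):
        entries = [
            TrainingEntry("A1", rfp({"X": 1}), ECLabel.parse("2.1.1")),
            TrainingEntry("A2", rfp({"X": 1, "Y": 1}), ECLabel.parse("2.1.1")),
            TrainingEntry("B1", rfp({"X": 1, "Y": -1}), ECLabel.parse("3.1.1")),
        ]
        # B1's nearest is A1 (sqrt 1... verify): brute distances
        assert euclidean_distance(entries[2].rfp, entries[0].rfp) == 1.0
        assert euclidean_distance(entries[2].rfp, entries[1].rfp) == 2.0
        report = _loocv_over_entries(entries)
        assert report.accuracy(3) == pytest.approx(2 / 3)

    def test_duplicated_dataset_is_perfectly_recovered(self, synthetic_set,
                                                       synthetic_graphs):
        entries = prepare_training(synthetic_set.reactions[:6],
                                   synthetic_graphs, 3)
        doubled = entries + [TrainingEntry(e.reaction_id + "-copy", e.rfp, e.ec)
                             for e in entries]
        report = _loocv_over_entries(doubled)
        assert report.accuracy(1) == report.accuracy(2) == report.accuracy(3) == 1.0

    def test_identical_pair_same_ec_scores_one(self, worked_compounds):
        a = Reaction("A", wx.R02910.reactants, wx.R02910.products,
                     ECLabel.parse("2.1.1"))
        b = Reaction("B", wx.R02910.reactants, wx.R02910.products,
                     ECLabel.parse("2.1.1"))
        report = loocv([a, b], worked_compounds, 3)
        assert report.accuracy(3) == 1.0
        assert all(r.min_distance == 0.0 for r in report.records)

    def test_zero_rfp_member_points_at_the_filter(self, worked_compounds):
        ok = Reaction("A", wx.R02910.reactants, wx.R02910.products,
                      ECLabel.parse("2.1.1"))
        with pytest.raises(ZeroFingerprintError, match="filter_dataset"):
            loocv([ok, wx.R00260], worked_compounds, 3)

    def test_template_recovery_on_default_synthetic_set(self, synthetic_set,
                                                        synthetic_graphs):
        report = loocv(synthetic_set.reactions, synthetic_graphs, 3)
        assert report.accuracy(3) == 1.0
        per_class = report.per_main_class()
        assert sum(n for n, _ in per_class.values()) == report.n
        assert set(per_class) == {1, 2, 3, 4}


def _loocv_over_entries(entries):
    records = []
    for i, e in enumerate(entries):
        rest = entries[:i] + entries[i + 1:]
        res = assign_ec(e.rfp, rest)
        records.append(PredictionRecord(
            e.reaction_id, e.ec, res.ec, res.min_distance,
            res.supporting_ids, res.tie_broken))
    return CVReport(tuple(records), max_len=3)


class TestLengthSweep:
    def test_shape_contract(self, synthetic_set, synthetic_graphs):
        rows = length_sweep(synthetic_set.reactions, synthetic_graphs, [0, 1, 2])
        assert [r.max_len for r in rows] == [0, 1, 2]
        for row in rows:
            assert row.n_kept + row.n_zero_excluded <= len(synthetic_set.reactions)

    def test_empty_lengths_list(self, synthetic_set, synthetic_graphs):
        assert length_sweep(synthetic_set.reactions, synthetic_graphs, []) == []

    def test_short_fragments_degrade_accuracy(self, synthetic_set,
                                              synthetic_graphs):
        """Methylation and amination share their length-1 difference
        fingerprint, so accuracy collapses below the discriminating length 2."""
        rows = length_sweep(synthetic_set.reactions, synthetic_graphs, [1, 2, 3])
        acc = [r.accuracy_sub_subclass for r in rows]
        assert acc[0] < acc[1] <= acc[2]
        assert acc[2] == 1.0

    def test_all_zero_length_gives_empty_row(self, synthetic_set,
                                             synthetic_graphs):
        # balanced reactions have no length-0 difference terms at all
        row = length_sweep(synthetic_set.reactions, synthetic_graphs, [0])[0]
        assert row.n_kept == 0
        assert math.isnan(row.accuracy_sub_subclass)


class TestDistanceBins:
    def _report(self, distances, correct_flags):
        records = tuple(
            PredictionRecord(
                f"R{i}", ECLabel.parse("2.1.1"),
                ECLabel.parse("2.1.1" if ok else "3.1.1"),
                d, ("T",), False)
            for i, (d, ok) in enumerate(zip(distances, correct_flags)))
        return CVReport(records, max_len=3)

    def test_all_zero_distances_land_in_first_bin(self):
        report = self._report([0.0] * 4, [True] * 4)
        bins = distance_binned_accuracy(report, [0, 10])
        assert bins[0].correct == 4
        assert bins[1].total == 0

    def test_counts_are_conserved(self, synthetic_set, synthetic_graphs):
        cv = loocv(synthetic_set.reactions, synthetic_graphs, 3)
        bins = distance_binned_accuracy(cv)
        assert sum(b.total for b in bins) == cv.n

    def test_known_distances_occupy_expected_bins(self):
        report = self._report([2.0, 15.0, 40.0], [True, True, False])
        bins = distance_binned_accuracy(report, [0, 10, 20, 50])
        assert [(b.correct, b.incorrect) for b in bins] == [
            (1, 0), (1, 0), (0, 1), (0, 0)]
        assert bins[-1].upper == math.inf

    def test_non_monotone_edges_rejected(self):
        report = self._report([1.0], [True])
        with pytest.raises(ClassifierError):
            distance_binned_accuracy(report, [0, 10, 10])
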