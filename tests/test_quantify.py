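import numpy as np
import pytest

from cgbesmart import quantify as qt
from cgbesmart import synthetic as syn
from cgbesmart.io_tables import EditPattern, OutcomeTable, ValidationError

from conftest import make_site

PROTO = "ACCTGACCTGACCTGACCTG"  # substrate Cs at 2,3,7,8,12,13,17,18


class TestOrientation:
    def test_forward_read_unchanged(self):
        site = make_site(PROTO)
        read = qt.Read("r", site.sequence, "forward")
        assert qt.orient_to_forward(read, site) is read

    def test_reverse_read_is_reverse_complemented(self):
        site = make_site(PROTO)
        read = qt.Read("r", syn.reverse_complement(site.sequence), "reverse")
        fwd = qt.orient_to_forward(read, site)
        assert fwd.sequence == site.sequence
        assert fwd.orientation == "forward"

    def test_orientation_is_idempotent(self):
        site = make_site(PROTO)
        read = qt.Read("r", syn.reverse_complement(site.sequence), "reverse")
        once = qt.orient_to_forward(read, site)
        assert qt.orient_to_forward(once, site) == once

    def test_unknown_orientation_errors(self):
        site = make_site(PROTO)
        with pytest.raises(ValidationError, match="orientation"):
            qt.orient_to_forward(qt.Read("r", site.sequence, "unknown"), site)

    def test_reverse_frame_positions_remap(self):
        assert qt.flip_positions({1, 6, 20}) == {20, 15, 1}


class TestClassifyRead:
    def test_reference_read_is_unedited(self):
        site = make_site(PROTO)
        assert qt.classify_read(site.sequence, site).kind == "unedited"

    def test_single_c_to_g_substitution(self):
        site = make_site(PROTO)
        seq = list(site.sequence)
        seq[site.seq_index(7)] = "G"
        call = qt.classify_read("".join(seq), site)
        assert call.kind == "substitution"
        assert call.substitutions == {7: "G"}

    def test_bystander_c_to_a_recorded(self):
        site = make_site(PROTO)
        seq = list(site.sequence)
        seq[site.seq_index(7)] = "G"
        seq[site.seq_index(12)] = "A"
        call = qt.classify_read("".join(seq), site)
        assert call.substitutions == {7: "G", 12: "A"}

    def test_deletion_in_protospacer_is_indel(self):
        site = make_site(PROTO)
        seq = list(site.sequence)
        del seq[site.seq_index(10)]
        assert qt.classify_read("".join(seq), site).kind == "indel"

    def test_insertion_in_protospacer_is_indel(self):
        site = make_site(PROTO)
        seq = list(site.sequence)
        seq.insert(site.seq_index(10), "T")
        assert qt.classify_read("".join(seq), site).kind == "indel"

    def test_read_not_covering_protospacer_errors(self):
        site = make_site(PROTO)
        fragment = site.sequence[: site.seq_index(8)]
        with pytest.raises(ValidationError, match="cover"):
            qt.classify_read(fragment, site)


class TestPerSiteStatistics:
    def _calls(self):
        sub = lambda d: qt.ReadCall("substitution", d)
        return (
            [sub({6: "G"})] * 3
            + [sub({6: "G", 8: "G"})]
            + [qt.ReadCall("indel")] * 2
            + [qt.ReadCall("unedited")] * 4
        )

    def test_on_target_counts_exact_pattern_over_all_reads(self):
        assert qt.on_target_efficiency(self._calls(), {(6, "G")}) == pytest.approx(0.3)

    def test_on_target_zero_and_one(self):
        unedited = [qt.ReadCall("unedited")] * 5
        assert qt.on_target_efficiency(unedited, {(6, "G")}) == 0.0
        exact = [qt.ReadCall("substitution", {6: "G"})] * 5
        assert qt.on_target_efficiency(exact, {(6, "G")}) == 1.0

    def test_indel_frequency(self):
        assert qt.indel_frequency(self._calls()) == pytest.approx(0.2)
        assert qt.indel_frequency([qt.ReadCall("unedited")]) == 0.0
        assert qt.indel_frequency([qt.ReadCall("indel")] * 3) == 1.0

    def test_empty_calls_error(self):
        with pytest.raises(ValidationError):
            qt.on_target_efficiency([], {(6, "G")})
        with pytest.raises(ValidationError):
            qt.indel_frequency([])

    def test_classes_partition_reads(self):
        calls = self._calls()
        on = qt.on_target_efficiency(calls, {(6, "G")})
        ind = qt.indel_frequency(calls)
        unedited = sum(c.kind == "unedited" for c in calls) / len(calls)
        bystander = (
            sum(
                c.kind == "substitution" and set(c.substitutions.items()) != {(6, "G")}
                for c in calls
            )
            / len(calls)
        )
        assert on + ind + unedited + bystander == pytest.approx(1.0)


class TestAssembleTrainingTable:
    def _site(self):
        return make_site(PROTO, "s1")

    def test_low_coverage_replicates_drop_site(self):
        site = self._site()
        reps = [
            OutcomeTable("s1", {EditPattern.ref(): 50, EditPattern.parse("2G"): 10}, "r1"),
            OutcomeTable("s1", {EditPattern.ref(): 60, EditPattern.parse("2G"): 20}, "r2"),
        ]
        tables, labels = qt.assemble_training_table(reps, {"s1": site})
        assert tables == {} and labels.empty

    def test_indel_removal_precedes_read_filter(self):
        # 95 clean + 10 indel reads: total 105 but only 95 after indel removal
        site = self._site()
        reps = [OutcomeTable("s1", {EditPattern.ref(): 95, EditPattern.indel(): 10}, "r1")]
        tables, _ = qt.assemble_training_table(reps, {"s1": site})
        assert tables == {}

    def test_surviving_replicates_summed_then_smoothed(self):
        site = self._site()
        reps = [
            OutcomeTable("s1", {EditPattern.ref(): 90, EditPattern.parse("2G"): 30}, "r1"),
            OutcomeTable("s1", {EditPattern.ref(): 100, EditPattern.parse("2G"): 40}, "r2"),
        ]
        tables, labels = qt.assemble_training_table(reps, {"s1": site})
        table = tables["s1"]
        assert table.counts[EditPattern.parse("2G")] == 71  # 30 + 40 + smoothing
        assert table.counts[EditPattern.ref()] == 190

    def test_unobserved_edited_outcome_has_count_one_after_smoothing(self):
        site = self._site()
        reps = [OutcomeTable("s1", {EditPattern.ref(): 200}, "r1")]
        tables, _ = qt.assemble_training_table(reps, {"s1": site})
        assert tables["s1"].counts[EditPattern.parse("7G")] == 1
        assert tables["s1"].counts[EditPattern.parse("2G+3G")] == 1

    def test_boundary_99_dropped_101_kept(self):
        site99 = make_site(PROTO, "s99")
        site101 = make_site(PROTO, "s101")
        reps = [
            OutcomeTable("s99", {EditPattern.ref(): 99}, "r1"),
            OutcomeTable("s101", {EditPattern.ref(): 101}, "r1"),
        ]
        tables, _ = qt.assemble_training_table(reps, {"s99": site99, "s101": site101})
        assert set(tables) == {"s101"}

    def test_replicate_order_invariance(self):
        site = self._site()
        reps = [
            OutcomeTable("s1", {EditPattern.ref(): 150, EditPattern.parse("2G"): 30}, "r1"),
            OutcomeTable("s1", {EditPattern.ref(): 220, EditPattern.parse("7G"): 11}, "r2"),
        ]
        t1, l1 = qt.assemble_training_table(reps, {"s1": site})
        t2, l2 = qt.assemble_training_table(reps[::-1], {"s1": site})
        assert t1["s1"].counts == t2["s1"].counts
        assert l1.sort_values(["site_id", "position"]).equals(
            l2.sort_values(["site_id", "position"])
        )

    def test_labels_converge_to_truth(self):
        # binomial concentration: |label - p| <= 4 se for >= 99% of labels
        cfg = syn.SimConfig(n_sites=150, seed=9, coverage_mean=2000, replicates=1)
        sites, truth = syn.simulate_library(cfg)
        tables = syn.simulate_reads(sites, truth, cfg)
        smap = {s.site_id: s for s in sites}
        _, labels = qt.assemble_training_table(tables, smap)
        within = [
            abs(row.efficiency - truth.efficiencies[(row.site_id, row.position)])
            <= 4
            * np.sqrt(
                truth.efficiencies[(row.site_id, row.position)]
                * (1 - truth.efficiencies[(row.site_id, row.position)])
                / row.coverage
            )
            for row in labels.itertuples(index=False)
        ]
        assert np.mean(within) >= 0.99


class TestWindowFilter:
    def test_window_and_coverage_rules(self):
        import pandas as pd

        labels = pd.DataFrame(
            {
                "site_id": ["s"] * 4,
                "position": [3, 5, 5, 6],
                "efficiency": [0.1] * 4,
                "coverage": [500, 100, 101, 2000],
            }
        )
        kept = qt.window_filter(labels)
        assert list(zip(kept["position"], kept["coverage"])) == [(5, 101), (6, 2000)]
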