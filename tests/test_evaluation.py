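"""Accuracy arithmetic, discordance bookkeeping and ambiguity analysis."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hlacall import (
    EXON23,
    GenotypeCall,
    TruthRecord,
    accuracy_table,
    ambiguity_report,
    discordance_table,
    feature_subsequence,
    group_by_feature_identity,
    match_genotype,
    parse_allele_name,
    project_to_exon23,
)
from hlacall.evaluation import round_pct


def name(t):
    return parse_allele_name(t)


def pair(a, b):
    return (name(a), name(b))


class TestMatchGenotype:
    def test_order_free_full_match(self):
        assert match_genotype(pair("A*02:01", "A*24:02"), pair("A*24:02", "A*02:01")) == 2

    def test_homozygous_truth_single_match(self):
        assert match_genotype(pair("A*26:01", "A*02:06"), pair("A*26:01", "A*26:01")) == 1

    def test_fail_matches_zero(self):
        assert match_genotype(None, pair("A*02:01", "A*24:02")) == 0

    def test_gene_mismatch_errors(self):
        with pytest.raises(ValueError):
            match_genotype(pair("A*02:01", "A*24:02"), pair("B*07:02", "B*08:01"))

    @given(idx=st.tuples(*[st.integers(0, 3)] * 4))
    @settings(derandomize=True, max_examples=256)
    def test_equals_exhaustive_pairing_max(self, idx):
        pool = [name(f"A*{i + 1:02d}:01") for i in range(4)]
        called = (pool[idx[0]], pool[idx[1]])
        truth = (pool[idx[2]], pool[idx[3]])
        brute = max(
            (c[0] == truth[0]) + (c[1] == truth[1])
            for c in itertools.permutations(called)
        )
        assert match_genotype(called, truth) == brute

    def test_symmetric_in_slot_order(self):
        called, truth = pair("A*02:01", "A*24:02"), pair("A*24:02", "A*26:01")
        assert match_genotype(called, truth) == match_genotype(called[::-1], truth[::-1])


def _records(gene, n_samples, miscalls):
    """n_samples concordant samples, then apply miscalls {sample_idx: (slot, wrong)}."""
    truths, calls = [], []
    for i in range(n_samples):
        s = f"S{i:03d}"
        t = pair(f"{gene}*01:01", f"{gene}*02:01")
        truths.append(TruthRecord(sample=s, gene=gene, alleles=t))
        called = list(t)
        action = miscalls.get(i)
        if action == "fail":
            calls.append(GenotypeCall(sample=s, gene=gene, status="fail"))
            continue
        if action is not None:
            slot, wrong = action
            called[slot] = name(wrong)
        calls.append(
            GenotypeCall(
                sample=s,
                gene=gene,
                status="called",
                alleles=tuple(called),
                support=(15.0, 15.0),
            )
        )
    return calls, truths


class TestAccuracyTable:
    def test_all_correct_is_100(self):
        for n_samples in (1, 7, 114):
            calls, truths = _records("A", n_samples, {})
            (row,) = accuracy_table(calls, truths)
            assert (row.n, row.n_correct, row.accuracy_pct) == (2 * n_samples, 2 * n_samples, 100.0)

    def test_228_slots_2_discordant_rounds_to_99_1(self):
        calls, truths = _records("A", 114, {0: (0, "A*02:06"), 1: (1, "A*03:01")})
        (row,) = accuracy_table(calls, truths)
        assert (row.n, row.n_correct) == (228, 226)
        assert row.accuracy_pct == 99.1  # 99.122... half-up to one decimal

    def test_228_slots_22_discordant_rounds_to_90_4(self):
        miscalls = {i: (0, "C*14:02") for i in range(22)}
        calls, truths = _records("C", 114, miscalls)
        (row,) = accuracy_table(calls, truths)
        assert (row.n, row.n_correct) == (228, 206)
        assert row.accuracy_pct == 90.4  # 90.350877... rounds up

    def test_rounding_is_half_up(self):
        assert round_pct(226, 228) == 99.1
        assert round_pct(224, 228) == 98.2  # 98.245...
        assert round_pct(206, 228) == 90.4
        assert round_pct(1997, 2000) == 99.9  # 99.85 exactly: half-up
        assert round_pct(228, 228) == 100.0

    def test_fail_costs_both_slots(self):
        calls, truths = _records("A", 10, {0: "fail"})
        (row,) = accuracy_table(calls, truths)
        assert (row.n, row.n_correct) == (20, 18)

    def test_missing_call_costs_both_slots(self):
        calls, truths = _records("A", 5, {})
        (row,) = accuracy_table(calls[:-1], truths)
        assert (row.n, row.n_correct) == (10, 8)

    def test_duplicate_calls_rejected(self):
        calls, truths = _records("A", 3, {})
        with pytest.raises(ValueError, match="duplicate"):
            accuracy_table(calls + [calls[0]], truths)


class TestDiscordanceTable:
    def test_all_correct_empty(self):
        calls, truths = _records("A", 20, {})
        assert discordance_table(calls, truths) == []

    def test_single_miscall_single_record(self):
        calls, truths = _records("A", 20, {3: (0, "A*02:06")})
        (rec,) = discordance_table(calls, truths)
        assert rec.gene == "A"
        assert rec.true_type == name("A*01:01")
        assert rec.called_type == name("A*02:06")
        assert rec.count == 1
        assert rec.truth_count == 20

    def test_injected_miscalls_recovered_exactly(self):
        injections = {1: (0, "A*05:01"), 4: (0, "A*05:01"), 9: (1, "A*07:01")}
        calls, truths = _records("A", 30, injections)
        recs = {(r.true_type.render(), r.called_type.render()): r.count
                for r in discordance_table(calls, truths)}
        assert recs == {("A*01:01", "A*05:01"): 2, ("A*02:01", "A*07:01"): 1}

    def test_fail_listed_per_slot(self):
        calls, truths = _records("A", 8, {2: "fail"})
        recs = discordance_table(calls, truths)
        assert {(r.true_type.render(), r.called_type) for r in recs} == {
            ("A*01:01", "fail"),
            ("A*02:01", "fail"),
        }

    def test_counts_sum_to_accuracy_deficit(self):
        injections = {0: "fail", 3: (0, "A*05:01"), 7: (1, "A*09:01")}
        calls, truths = _records("A", 25, injections)
        (row,) = accuracy_table(calls, truths)
        total = sum(r.count for r in discordance_table(calls, truths))
        assert total == row.n - row.n_correct


class TestExon23Projection:
    @pytest.fixture(autouse=True)
    def groups(self, small_panel):
        self.panel = small_panel
        self.groups = {
            g: group_by_feature_identity(small_panel, g, EXON23)
            for g in small_panel.genes()
        }

    def test_singleton_projects_to_itself(self):
        truth = TruthRecord("s", "A", pair("A*03:01", "A*03:01"))
        assert project_to_exon23(truth, self.groups["A"]) == {name("A*03:01")}

    def test_twin_member_projects_to_both(self):
        truth = TruthRecord("s", "A", pair("A*01:82", "A*01:82"))
        assert project_to_exon23(truth, self.groups["A"]) == {name("A*01:01"), name("A*01:82")}

    def test_matches_sequence_level_recomputation(self):
        # brute-force from sequences, independent of the grouping code
        truth = TruthRecord("s", "A", pair("A*01:01", "A*04:01"))
        projected = project_to_exon23(truth, self.groups["A"])
        expected = set()
        for t in truth.alleles:
            t_sub = feature_subsequence(self.panel.by_name(t), EXON23)
            for a in self.panel.gene_alleles("A"):
                if feature_subsequence(a, EXON23) == t_sub:
                    expected.add(a.name)
        assert projected == expected

    def test_absent_allele_errors(self):
        truth = TruthRecord("s", "A", pair("A*77:77", "A*01:01"))
        with pytest.raises(KeyError):
            project_to_exon23(truth, self.groups["A"])


class TestAmbiguityReport:
    @pytest.fixture(autouse=True)
    def groups(self, small_panel):
        self.panel = small_panel
        self.groups = {
            g: group_by_feature_identity(small_panel, g, EXON23)
            for g in small_panel.genes()
        }

    def _call(self, sample, gene, a, b):
        return GenotypeCall(
            sample=sample, gene=gene, status="called",
            alleles=tuple(sorted(pair(a, b))), support=(15.0, 15.0),
        )

    def test_twin_conflict_flagged_as_same_group(self):
        # one method reads only exons 2+3 and reports the twin's partner
        ngs = [TruthRecord("s1", "A", pair("A*01:82", "A*03:01"))]
        luminex = [TruthRecord("s1", "A", pair("A*01:01", "A*03:01"))]
        calls = [self._call("s1", "A", "A*01:82", "A*03:01")]
        (rep,) = ambiguity_report(ngs, luminex, calls, self.groups)
        assert rep.same_exon23_group is True
        assert {rep.type_a, rep.type_b} == {name("A*01:82"), name("A*01:01")}
        assert rep.resolving_call == name("A*01:82")

    def test_conflict_within_exon2_not_same_group(self):
        ngs = [TruthRecord("s1", "A", pair("A*02:01", "A*03:01"))]
        luminex = [TruthRecord("s1", "A", pair("A*04:01", "A*03:01"))]
        calls = [self._call("s1", "A", "A*02:01", "A*03:01")]
        (rep,) = ambiguity_report(ngs, luminex, calls, self.groups)
        assert rep.same_exon23_group is False

    def test_no_conflicts_empty_report(self):
        ngs = [TruthRecord("s1", "A", pair("A*02:01", "A*03:01"))]
        calls = [self._call("s1", "A", "A*02:01", "A*03:01")]
        assert ambiguity_report(ngs, list(ngs), calls, self.groups) == []

    def test_allele_absent_from_panel_marked_unknown(self):
        ngs = [TruthRecord("s1", "A", pair("A*88:01", "A*03:01"))]
        luminex = [TruthRecord("s1", "A", pair("A*02:01", "A*03:01"))]
        calls = [self._call("s1", "A", "A*02:01", "A*03:01")]
        (rep,) = ambiguity_report(ngs, luminex, calls, self.groups)
        assert rep.same_exon23_group is None
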