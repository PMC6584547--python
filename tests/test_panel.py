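"""Nomenclature parsing, panel merging and exon-2/3 identity grouping."""

import pytest
from hypothesis import given, settings, strategies as st

from hlacall import (
    AlleleName,
    AlleleSequence,
    Feature,
    PanelSpec,
    ReferencePanel,
    exon_only_panel,
    feature_subsequence,
    group_by_feature_identity,
    make_panel,
    merge_panels,
    parse_allele_name,
    read_panel,
    truncate_resolution,
    write_panel,
)
from hlacall.panel import AlleleNameError, FeatureError, PanelConflictError, EXON23


class TestParseAlleleName:
    @pytest.mark.parametrize(
        "text, gene, fields, suffix, g_group",
        [
            ("A*02:15N", "A", ("02", "15"), "N", False),
            ("A*02:15 N", "A", ("02", "15"), "N", False),  # detached suffix
            ("A*01:01:01G", "A", ("01", "01", "01"), "", True),
            ("A*01:01:01 G", "A", ("01", "01", "01"), "", True),
            ("B*15:428", "B", ("15", "428"), "", False),
            ("C*04:82", "C", ("04", "82"), "", False),
            ("DRB1*04:05:01:02", "DRB1", ("04", "05", "01", "02"), "", False),
        ],
    )
    def test_examples(self, text, gene, fields, suffix, g_group):
        name = parse_allele_name(text)
        assert (name.gene, name.fields, name.suffix, name.g_group) == (
            gene,
            fields,
            suffix,
            g_group,
        )

    @pytest.mark.parametrize("bad", ["A02:01", "A*xx:01", "", "A*", "A*01:01:01:01:01"])
    def test_malformed(self, bad):
        with pytest.raises(AlleleNameError):
            parse_allele_name(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(AlleleNameError, match="xx"):
            parse_allele_name("A*xx:01")

    @given(
        gene=st.sampled_from(["A", "B", "C", "DRB1"]),
        fields=st.lists(
            st.integers(0, 999).map(lambda v: f"{v:02d}"), min_size=1, max_size=4
        ),
        suffix=st.sampled_from(["", "N", "L", "S", "C", "A", "Q"]),
        g_group=st.booleans(),
    )
    @settings(derandomize=True, max_examples=200)
    def test_render_parse_roundtrip(self, gene, fields, suffix, g_group):
        name = AlleleName(gene=gene, fields=tuple(fields), suffix=suffix, g_group=g_group)
        assert parse_allele_name(name.render()) == name


class TestTruncateResolution:
    def test_prefix_rule(self):
        assert truncate_resolution(parse_allele_name("A*26:03:01"), 2).render() == "A*26:03"

    def test_suffix_kept(self):
        name = parse_allele_name("A*02:15N")
        assert truncate_resolution(name, 2) == name

    def test_fewer_fields_unchanged(self):
        name = parse_allele_name("C*04:82")
        assert truncate_resolution(name, 3) == name

    def test_bad_resolution(self):
        with pytest.raises(ValueError):
            truncate_resolution(parse_allele_name("A*01:01"), 0)


def _allele(name, seq, features=(), source="base"):
    return AlleleSequence(
        name=parse_allele_name(name), seq=seq, features=list(features), source=source
    )


class TestMergePanels:
    def setup_method(self):
        self.base = ReferencePanel(
            alleles=[_allele("A*01:01", "ACGTACGTAC"), _allele("A*02:01", "ACGTTCGTAC")]
        )

    def test_merge_with_empty_is_identity(self):
        merged = merge_panels(self.base, ReferencePanel())
        assert merged.names == self.base.names
        assert merged.aliases == {}

    def test_duplicate_sequence_recorded_as_alias(self):
        pop = ReferencePanel(alleles=[_allele("A*01:99", "ACGTACGTAC", source="population")])
        merged = merge_panels(self.base, pop)
        assert len(merged) == len(self.base)
        assert merged.aliases == {"A*01:99": "A*01:01"}
        # alias resolves through lookup
        assert merged.by_name("A*01:99").name.render() == "A*01:01"

    def test_novel_sequence_appended_with_population_source(self):
        pop = ReferencePanel(alleles=[_allele("A*03:01", "TTTTACGTAC")])
        merged = merge_panels(self.base, pop)
        assert len(merged) == len(self.base) + 1
        assert merged.by_name("A*03:01").source == "population"

    def test_same_name_different_sequence_conflicts(self):
        pop = ReferencePanel(alleles=[_allele("A*01:01", "GGGGGGGGGG")])
        with pytest.raises(PanelConflictError, match="A\\*01:01"):
            merge_panels(self.base, pop)

    def test_idempotent(self):
        pop = ReferencePanel(
            alleles=[
                _allele("A*01:99", "ACGTACGTAC"),
                _allele("A*03:01", "TTTTACGTAC"),
            ]
        )
        once = merge_panels(self.base, pop)
        twice = merge_panels(once, pop)
        assert twice.names == once.names
        assert twice.aliases == once.aliases


class TestFeatureSubsequence:
    def setup_method(self):
        seq = "".join("ACGT"[i % 4] for i in range(50))
        self.allele = _allele(
            "A*01:01",
            seq,
            features=[
                Feature("exon", 1, 0, 10),
                Feature("intron", 1, 10, 30),
                Feature("exon", 2, 30, 40),
                Feature("exon", 3, 40, 50),
            ],
        )

    def test_concatenation(self):
        sub = feature_subsequence(self.allele, [("exon", 2), ("exon", 3)])
        assert sub == self.allele.seq[30:40] + self.allele.seq[40:50]
        assert len(sub) == 20

    def test_order_respected(self):
        ab = feature_subsequence(self.allele, [("exon", 2), ("exon", 1)])
        assert ab == self.allele.seq[30:40] + self.allele.seq[0:10]

    def test_empty_request(self):
        assert feature_subsequence(self.allele, []) == ""

    def test_missing_feature_errors(self):
        with pytest.raises(FeatureError, match="exon 9"):
            feature_subsequence(self.allele, [("exon", 9)])


class TestGroupByFeatureIdentity:
    def brute_force(self, panel, gene):
        """O(M^2) all-pairs comparison partition."""
        alleles = panel.gene_alleles(gene)
        subs = {a.name: feature_subsequence(a, EXON23) for a in alleles}
        groups = []
        for name, sub in subs.items():
            for g in groups:
                if subs[next(iter(g))] == sub:
                    g.add(name)
                    break
            else:
                groups.append({name})
        return {frozenset(g) for g in groups}

    def test_twin_pair_shares_group(self, small_panel):
        for gene in small_panel.genes():
            groups = group_by_feature_identity(small_panel, gene)
            multi = [g for g in groups if len(g) > 1]
            assert len(multi) == 1
            names = sorted(m.render() for m in multi[0].members)
            assert names == [f"{gene}*01:01", f"{gene}*01:82"]

    def test_partition_matches_brute_force_on_random_panel(self):
        panel = make_panel(PanelSpec(n_genes=1, alleles_per_gene=30, n_exon23_twins=3, seed=23))
        gene = panel.genes()[0]
        groups = group_by_feature_identity(panel, gene)
        assert {frozenset(g.members) for g in groups} == self.brute_force(panel, gene)

    def test_partition_is_disjoint_and_covering(self, small_panel):
        gene = small_panel.genes()[0]
        groups = group_by_feature_identity(small_panel, gene)
        seen = [m for g in groups for m in g.members]
        assert len(seen) == len(set(seen)) == len(small_panel.gene_alleles(gene))

    def test_groups_sorted_by_smallest_member(self, small_panel):
        gene = small_panel.genes()[0]
        groups = group_by_feature_identity(small_panel, gene)
        keys = [g.smallest.sort_key() for g in groups]
        assert keys == sorted(keys)


class TestPanelIO:
    def test_fasta_and_sidecar_roundtrip(self, small_panel, tmp_path):
        fasta = tmp_path / "panel.fa"
        feats = tmp_path / "features.tsv"
        write_panel(small_panel, fasta, features=feats)
        back = read_panel(fasta, features=feats)
        assert back.names == small_panel.names
        a0, b0 = small_panel.alleles[0], back.alleles[0]
        assert a0.seq == b0.seq
        assert a0.features == b0.features

    def test_deterministic_fasta_bytes(self, tmp_path):
        spec = PanelSpec(n_genes=1, alleles_per_gene=5, seed=1)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_panel(make_panel(spec), p1)
        write_panel(make_panel(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestExonOnlyPanel:
    def test_truncation_keeps_exons_drops_introns(self, small_panel):
        exon = exon_only_panel(small_panel)
        full = small_panel.alleles[0]
        trunc = exon.by_name(full.name)
        expected = "".join(
            full.seq[f.start : f.end] for f in full.features if f.kind == "exon"
        )
        assert trunc.seq == expected
        assert all(f.kind == "exon" for f in trunc.features)
        assert not trunc.full_length

    def test_twins_become_identical_sequences(self, small_panel):
        exon = exon_only_panel(small_panel)
        gene = exon.genes()[0]
        twin_a = exon.by_name(f"{gene}*01:01")
        twin_b = exon.by_name(f"{gene}*01:82")
        assert twin_a.seq == twin_b.seq
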