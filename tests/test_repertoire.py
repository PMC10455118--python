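"""Repertoire aggregation, substrate totals, uniqueness, and ortholog merging."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cazkit import (
    GeneAnnotation,
    OrthologGroupSet,
    count_families,
    merge_ortholog_groups,
    substrate_totals,
    uniqueness_report,
)
from cazkit.catalog import parse_family_key


def ann(gene, species, family):
    return GeneAnnotation(gene_id=gene, species=species, family=parse_family_key(family))


class TestCountFamilies:
    def test_two_gh6_genes_counted(self, catalog):
        rep = count_families([ann("a", "A.niger", "GH6"), ann("b", "A.niger", "GH6")], catalog)
        assert rep.counts.loc["A.niger", "GH6"] == 2

    def test_empty_input_gives_empty_matrix(self, catalog):
        rep = count_families([], catalog)
        assert rep.counts.size == 0 and rep.off_catalog.size == 0

    def test_row_sum_equals_gene_count(self, catalog):
        anns = [ann("a", "sp", "GH6"), ann("b", "sp", "GH7"), ann("c", "sp", "GH6")]
        rep = count_families(anns, catalog)
        assert rep.counts.loc["sp"].sum() == 3

    def test_duplicate_gene_rejected(self, catalog):
        anns = [ann("a", "sp", "GH6"), ann("a", "sp", "GH7")]
        with pytest.raises(ValueError, match="duplicate"):
            count_families(anns, catalog)

    def test_same_gene_id_in_two_species_allowed(self, catalog):
        rep = count_families([ann("a", "sp1", "GH6"), ann("a", "sp2", "GH6")], catalog)
        assert rep.counts["GH6"].sum() == 2

    def test_off_catalog_known_class_family(self, catalog):
        # GH999 parses but is not in the catalog: side table, not main matrix
        anns = [ann("a", "sp", "GH6"), ann("b", "sp", "GH999")]
        rep = count_families(anns, catalog)
        assert "GH999" not in rep.counts.columns
        assert rep.off_catalog.loc["sp", "GH999"] == 1
        assert rep.counts.to_numpy().sum() == 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from(["sp1", "sp2", "sp3"]),
                  st.sampled_from(["GH6", "GH7", "GH11", "CE8", "FAE"])),
        max_size=30,
    ))
    def test_matches_brute_force_tally(self, catalog, pairs):
        anns = [ann(f"g{i}", sp, fam) for i, (sp, fam) in enumerate(pairs)]
        rep = count_families(anns, catalog)
        oracle = Counter((sp, fam) for sp, fam in pairs)
        for (sp, fam), n in oracle.items():
            assert rep.counts.loc[sp, fam] == n
        assert rep.counts.to_numpy().sum() == len(pairs)


class TestSubstrateTotals:
    def test_gh32_counts_only_inulin(self, catalog):
        rep = count_families([ann(f"g{i}", "sp", "GH32") for i in range(5)], catalog)
        totals = substrate_totals(rep, catalog)
        assert totals.loc["sp", "inulin"] == 5
        assert totals.loc["sp"].drop("inulin").sum() == 0

    def test_multifunctional_gene_counted_per_substrate(self, catalog):
        rep = count_families([ann("g", "sp", "GH12")], catalog)
        totals = substrate_totals(rep, catalog)
        assert totals.loc["sp", "cellulose"] == 1
        assert totals.loc["sp", "xyloglucan"] == 1

    def test_empty_repertoire_zero_table(self, catalog):
        totals = substrate_totals(count_families([], catalog), catalog)
        assert totals.size == 0 or (totals.to_numpy() == 0).all()

    def test_linearity_under_concatenation(self, catalog):
        rng = np.random.default_rng(11)
        fams = ["GH6", "GH12", "GH43", "GH32", "CE16", "FAE"]
        a = [ann(f"a{i}", "sp", rng.choice(fams)) for i in range(20)]
        b = [ann(f"b{i}", "sp", rng.choice(fams)) for i in range(15)]
        ta = substrate_totals(count_families(a, catalog), catalog)
        tb = substrate_totals(count_families(b, catalog), catalog)
        tab = substrate_totals(count_families(a + b, catalog), catalog)
        combined = ta.add(tb, fill_value=0).astype(int)
        assert tab.loc["sp"].equals(combined.loc["sp"])


class TestUniqueness:
    GROUPING = {"sp1": "Asco", "sp2": "Asco", "sp3": "Basidio"}

    def test_species_unique_family(self, catalog):
        anns = [ann("a", "sp1", "GH44"), ann("b", "sp2", "GH6"), ann("c", "sp3", "GH6")]
        rep = count_families(anns, catalog)
        report = uniqueness_report(rep, self.GROUPING)
        assert report.species_unique[parse_family_key("GH44")] == "sp1"

    def test_group_exclusive_not_species_unique(self, catalog):
        anns = [
            ann("a", "sp1", "GH54"), ann("b", "sp2", "GH54"),
            ann("c", "sp3", "GH6"), ann("d", "sp1", "GH6"), ann("e", "sp2", "GH6"),
        ]
        report = uniqueness_report(count_families(anns, catalog), self.GROUPING)
        key = parse_family_key("GH54")
        assert report.group_exclusive[key] == "Asco"
        assert key not in report.species_unique

    def test_ubiquitous_family_in_neither_list(self, catalog):
        anns = [ann(f"g{i}", sp, "GH6") for i, sp in enumerate(self.GROUPING)]
        report = uniqueness_report(count_families(anns, catalog), self.GROUPING)
        key = parse_family_key("GH6")
        assert key not in report.species_unique
        assert key not in report.group_exclusive

    def test_missing_grouping_errors(self, catalog):
        rep = count_families([ann("a", "spX", "GH6")], catalog)
        with pytest.raises(ValueError, match="spX"):
            uniqueness_report(rep, self.GROUPING)


def brute_force_merge(a, b):
    """Union-find oracle over the union of co-membership relations."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for gs in (a, b):
        for group in gs.groups:
            members = sorted(group)
            for m in members:
                union(members[0], m)
    out = {}
    for x in list(parent):
        out.setdefault(find(x), set()).add(x)
    return {frozenset(v) for v in out.values()}


def as_set(gs: OrthologGroupSet):
    return set(gs.groups)


group_sets = st.lists(
    st.lists(st.integers(0, 12), min_size=1, max_size=4, unique=True), max_size=5
).map(lambda gps: _disjointify(gps))


def _disjointify(gps):
    seen, out = set(), []
    for gp in gps:
        gp = [g for g in gp if g not in seen]
        if gp:
            out.append(frozenset(gp))
            seen.update(gp)
    return OrthologGroupSet(groups=tuple(out), source="h")


class TestMergeOrthologGroups:
    def test_idempotent_on_identical_inputs(self):
        a = OrthologGroupSet(groups=(frozenset({"x", "y"}), frozenset({"z"})), source="a")
        assert as_set(merge_ortholog_groups(a, a)) == as_set(a)

    def test_chained_groups_connect(self):
        a = OrthologGroupSet(groups=(frozenset({"x", "y"}),), source="a")
        b = OrthologGroupSet(groups=(frozenset({"y", "z"}),), source="b")
        assert as_set(merge_ortholog_groups(a, b)) == {frozenset({"x", "y", "z"})}

    def test_disjoint_universes_concatenate(self):
        a = OrthologGroupSet(groups=(frozenset({"x", "y"}),), source="a")
        b = OrthologGroupSet(groups=(frozenset({"u", "v"}),), source="b")
        assert as_set(merge_ortholog_groups(a, b)) == {frozenset({"x", "y"}), frozenset({"u", "v"})}

    def test_non_disjoint_input_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            OrthologGroupSet(groups=(frozenset({"x", "y"}), frozenset({"y", "z"})), source="a")

    @settings(max_examples=100, deadline=None)
    @given(group_sets, group_sets)
    def test_matches_union_find_oracle(self, a, b):
        merged = merge_ortholog_groups(a, b)
        assert as_set(merged) == brute_force_merge(a, b)
        # every input gene appears exactly once
        assert merged.genes == a.genes | b.genes
        assert sum(len(g) for g in merged.groups) == len(merged.genes)

    @settings(max_examples=50, deadline=None)
    @given(group_sets, group_sets)
    def test_commutative(self, a, b):
        assert as_set(merge_ortholog_groups(a, b)) == as_set(merge_ortholog_groups(b, a))

    @settings(max_examples=50, deadline=None)
    @given(group_sets, group_sets, group_sets)
    def test_associative(self, a, b, c):
        left = merge_ortholog_groups(merge_ortholog_groups(a, b), c)
        right = merge_ortholog_groups(a, merge_ortholog_groups(b, c))
        assert as_set(left) == as_set(right)
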