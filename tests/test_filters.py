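"""The stringency cascade: singleton removal, threshold filters, retention."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylofilt import (
    StringencyLevel,
    ValidationError,
    aggregate_to_phylotypes,
    apply_stringency,
    core_across_levels,
    mean_replicate_retention,
    per_replicate_analysis,
    remove_singletons,
    retention_percent,
    retention_report,
    run_cascade,
    standard_levels,
)
from tests.conftest import make_otus


def unique_lineage(i: int) -> str:
    return f"Bacteria;phy{i % 5};cls{i % 7};ord{i % 11};fam{i % 13};gen{i};gen{i} sp. {i}"


def table_from_counts(count_rows, shared_labels=False):
    """One OTU per row; unique lineages unless shared_labels pools them."""
    rows = {f"otu{i}": tuple(c) for i, c in enumerate(count_rows)}
    taxonomy = {
        f"otu{i}": unique_lineage(i % 8 if shared_labels else i) for i in range(len(count_rows))
    }
    return make_otus(rows, taxonomy)


def oracle_survivors(count_rows, labels, level: StringencyLevel) -> set:
    """Brute-force set-comprehension evaluation of the stringency rules,
    working directly on plain lists, independent of the implementation."""
    n_reps = len(count_rows[0]) if count_rows else 3
    rows = [list(c) for c in count_rows]
    if level.remove_singletons:
        rows = [[0 if c == 1 else c for c in row] for row in rows]
    ptotals: dict[str, list[int]] = {}
    for row, label in zip(rows, labels):
        acc = ptotals.setdefault(label, [0] * n_reps)
        for r in range(n_reps):
            acc[r] += row[r]
    return {
        label
        for label, counts in ptotals.items()
        if sum(c >= level.min_count for c in counts) >= level.min_replicates
    }


# --- remove_singletons ------------------------------------------------------


def test_all_singleton_row_is_dropped():
    table = table_from_counts([(1, 1, 1)])
    assert len(remove_singletons(table)) == 0


def test_singleton_cells_zeroed_per_replicate():
    table = table_from_counts([(5, 1, 0)])
    out = remove_singletons(table)
    assert out.counts.loc["otu0"].tolist() == [5, 0, 0]


def test_empty_table_stays_empty():
    table = table_from_counts([])
    assert len(remove_singletons(table)) == 0


@given(st.lists(st.tuples(*[st.integers(0, 12)] * 3), min_size=1, max_size=30))
def test_singleton_removal_mass_loss_equals_singleton_cells(count_rows):
    table = table_from_counts(count_rows)
    removed = table.total_counts - remove_singletons(table).total_counts
    n_ones = sum(c == 1 for row in count_rows for c in row)
    assert removed == n_ones


# --- apply_stringency rule enumeration --------------------------------------


@pytest.mark.parametrize(
    "counts,kept_at",
    [
        ((10, 0, 0), {"T0", "T1", "T10"}),
        ((10, 12, 9), {"T0", "T1", "T10", "T10-R1"}),
        ((1, 1, 1), {"T0"}),
        ((10, 10, 10), {"T0", "T1", "T10", "T10-R1", "T10-R2"}),
    ],
)
def test_level_rules_on_single_phylotype(counts, kept_at):
    table = table_from_counts([counts])
    ptab = aggregate_to_phylotypes(table)
    for name, level in standard_levels(3).items():
        out = apply_stringency(ptab, level, source_otus=table)
        assert (len(out) == 1) == (name in kept_at), name


def test_min_replicates_beyond_replicate_count_is_an_error():
    table = table_from_counts([(5, 5, 5)])
    ptab = aggregate_to_phylotypes(table)
    with pytest.raises(ValidationError):
        apply_stringency(ptab, StringencyLevel("bad", 10, 4), source_otus=table)


@given(
    st.lists(st.tuples(*[st.integers(0, 30)] * 3), min_size=1, max_size=50),
    st.booleans(),
)
def test_apply_stringency_matches_brute_force_oracle(count_rows, shared):
    table = table_from_counts(count_rows, shared_labels=shared)
    labels = [str(aggregate_to_phylotypes(table.select([o])).counts.index[0]) for o in table.otu_ids]
    ptab = aggregate_to_phylotypes(table)
    for level in standard_levels(3).values():
        got = {str(p) for p in apply_stringency(ptab, level, source_otus=table).labels}
        assert got == oracle_survivors(count_rows, labels, level), level.name


@given(st.lists(st.tuples(*[st.integers(0, 25)] * 3), min_size=1, max_size=40))
def test_stringency_sets_nest(count_rows):
    table = table_from_counts(count_rows)
    sets = run_cascade(table).phylotype_sets()
    assert sets["T10-R2"] <= sets["T10-R1"] <= sets["T10"] <= sets["T1"] <= sets["T0"]


# --- retention reporting ----------------------------------------------------


def test_prokaryote_t1_retention_is_59_19_percent():
    """1409 baseline phylotypes of which 834 survive singleton removal."""
    rows = [(2, 0, 0)] * 834 + [(1, 0, 0)] * 575
    cascade = run_cascade(table_from_counts(rows))
    report = retention_report(cascade)
    assert report.levels["T0"].phylotype_count == 1409
    assert report.levels["T0"].pct_phylotypes_retained == 100.00
    assert report.levels["T1"].phylotype_count == 834
    assert report.levels["T1"].pct_phylotypes_retained == 59.19


def test_eukaryote_t1_retention_is_72_54_percent():
    rows = [(3, 0, 0)] * 346 + [(0, 1, 0)] * 131
    report = retention_report(run_cascade(table_from_counts(rows)))
    assert report.levels["T0"].phylotype_count == 477
    assert report.levels["T1"].phylotype_count == 346
    assert report.levels["T1"].pct_phylotypes_retained == 72.54


def test_identical_baseline_and_filtered_table_is_100_percent():
    rows = [(20, 20, 20)] * 10
    report = retention_report(run_cascade(table_from_counts(rows)))
    for stats in report.levels.values():
        assert stats.pct_phylotypes_retained == 100.00
        assert stats.pct_reads_retained == 100.00


def test_empty_baseline_is_an_error():
    cascade = run_cascade(table_from_counts([(2, 2, 2)]))
    cascade.phylotype_tables["T0"] = apply_stringency(
        cascade.phylotype_tables["T0"],
        StringencyLevel("wipe", 10**6, 1),
    )
    with pytest.raises(ValidationError):
        retention_report(cascade)


def test_mean_replicate_retention_matches_reported_percentages():
    """Replicate-wise singleton filtering averages 65% (prokaryotes) and
    79% (eukaryotes) over the three reference count pairs."""
    assert mean_replicate_retention([(882, 561), (1077, 697), (767, 505)]) == 65
    assert mean_replicate_retention([(339, 267), (353, 279), (346, 278)]) == 79


def test_retention_percent_rounds_half_away():
    assert retention_percent(1409, 834) == 59.19
    assert retention_percent(477, 346) == 72.54
    assert retention_percent(10000, 55) == 0.55
    assert retention_percent(800, 5) == 0.63  # 0.625 rounds away from zero


# --- cross-level core and per-replicate analysis ----------------------------


def test_core_of_nested_sets_is_smallest_set():
    sets = {"T0": {"a", "b", "c"}, "T1": {"a", "b"}, "T10": {"a"}}
    assert core_across_levels(sets) == {"a"}


def test_core_of_disjoint_sets_is_empty():
    assert core_across_levels({"x": {"a"}, "y": {"b"}}) == set()


@given(st.lists(st.tuples(*[st.integers(0, 25)] * 3), min_size=1, max_size=30))
def test_core_equals_most_stringent_level_by_nesting(count_rows):
    table = table_from_counts(count_rows)
    sets = run_cascade(table).phylotype_sets()
    if len(sets["T0"]) == 0:
        return
    assert core_across_levels(sets) == sets["T10-R2"]


def test_per_replicate_t1_uses_single_replicate_counts():
    # phylotype A is a singleton in rep1, B is not
    table = make_otus(
        {"A": (1, 0, 0), "B": (5, 0, 0)},
        {"A": unique_lineage(0), "B": unique_lineage(1)},
    )
    sets, _venn = per_replicate_analysis(table, StringencyLevel.from_name("T1"))
    assert {str(p) for p in sets["rep1"]} == {"gen1 sp. 1"}
    assert sets["rep2"] == set() and sets["rep3"] == set()


def test_identical_replicates_land_in_shared_region():
    table = table_from_counts([(4, 4, 4), (7, 7, 7)])
    sets, venn = per_replicate_analysis(table, StringencyLevel.from_name("T0"))
    assert venn.size("rep1", "rep2", "rep3") == 2
    assert venn.union_size == 2


@settings(max_examples=30)
@given(st.lists(st.tuples(*[st.integers(0, 15)] * 3), min_size=1, max_size=25))
def test_per_replicate_venn_partitions_the_union(count_rows):
    table = table_from_counts(count_rows)
    sets, venn = per_replicate_analysis(table, StringencyLevel.from_name("T1"))
    union = set().union(*sets.values())
    assert venn.union_size == len(union)
    total = sum(len(v) for v in venn.regions.values())
    assert total == len(union)
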