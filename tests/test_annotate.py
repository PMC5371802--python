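"""Top-hit selection, taxonomy assignment and method comparison."""

import random

import pytest
from hypothesis import given, strategies as st

from phylofilt import (
    BlastHit,
    Lineage,
    TaxonomyMap,
    ValidationError,
    annotate,
    method_overlap,
    subsample,
    superkingdom_profile,
    top_hit_per_query,
)


def hit(q="q1", s="s1", bits=100.0, ev=1e-10):
    return BlastHit(q, s, 98.0, 80, 1, 0, 1, 80, 1, 80, ev, bits)


def test_top_hit_is_max_bit_score():
    best = top_hit_per_query([hit(bits=90.0, s="lo"), hit(bits=100.0, s="hi")])
    assert best["q1"].subject_id == "hi"


def test_bit_score_tie_broken_by_min_evalue():
    best = top_hit_per_query(
        [hit(bits=80.0, ev=1e-20, s="worse"), hit(bits=80.0, ev=1e-30, s="better")]
    )
    assert best["q1"].subject_id == "better"


def test_full_tie_broken_by_input_order():
    best = top_hit_per_query([hit(s="first"), hit(s="second")])
    assert best["q1"].subject_id == "first"


def test_single_hit_query_returns_it():
    best = top_hit_per_query([hit(q="solo", s="only")])
    assert best["solo"].subject_id == "only"


def test_shuffle_invariance_with_tie_free_scores():
    hits = [hit(q=f"q{i}", s=f"s{i}{j}", bits=50.0 + 10 * j + i) for i in range(5) for j in range(3)]
    expected = {q: h.subject_id for q, h in top_hit_per_query(hits).items()}
    rng = random.Random(7)
    for _ in range(5):
        rng.shuffle(hits)
        got = {q: h.subject_id for q, h in top_hit_per_query(hits).items()}
        assert got == expected


def test_annotate_lookup_miss_and_unannotated():
    taxmap = TaxonomyMap(
        {
            "s_bact": Lineage.from_labels(["Bacteria", "p", "c", "o", "f", "g"]),
        }
    )
    tophits = {
        "q_hit": hit(q="q_hit", s="s_bact"),
        "q_miss": hit(q="q_miss", s="s_unknown"),
    }
    ann = annotate(tophits, taxmap, queries=["q_hit", "q_miss", "q_nohit"])
    assert ann.lineage_of("q_hit").labels[0] == "Bacteria"
    assert ann.lineage_of("q_miss").is_empty
    assert ann.n_unknown_subject == 1
    assert ann.unannotated == ["q_nohit"]


def test_superkingdom_profile_counts_unknowns():
    taxmap = TaxonomyMap({f"s{i}": Lineage.from_labels(["Bacteria", "p"]) for i in range(3)})
    tophits = {f"q{i}": hit(q=f"q{i}", s=f"s{i}") for i in range(3)}
    tophits["q_unk"] = hit(q="q_unk", s="missing")
    profile = superkingdom_profile(annotate(tophits, taxmap))
    assert profile == {"Bacteria": 75.00, "unknown": 25.00}


def test_profile_of_single_category_is_100():
    taxmap = TaxonomyMap({"s": Lineage.from_labels(["Viruses"])})
    profile = superkingdom_profile(annotate({"q": hit(s="s")}, taxmap))
    assert profile == {"Viruses": 100.00}


def test_empty_annotation_set_gives_empty_profile():
    from phylofilt.annotate import AnnotationSet

    assert superkingdom_profile(AnnotationSet()) == {}


@given(st.lists(st.sampled_from(["Bacteria", "Archaea", "Eukaryota", "Viruses"]), min_size=1, max_size=60))
def test_profile_percentages_sum_to_100(cats):
    taxmap = TaxonomyMap(
        {f"s{i}": Lineage.from_labels([c]) for i, c in enumerate(cats)}
    )
    tophits = {f"q{i}": hit(q=f"q{i}", s=f"s{i}") for i in range(len(cats))}
    profile = superkingdom_profile(annotate(tophits, taxmap))
    assert abs(sum(profile.values()) - 100.0) <= 0.05


# --- subsampling ------------------------------------------------------------


def test_subsample_saturates_in_original_order():
    items = ["a", "b", "c"]
    assert subsample(items, 10, seed=1) == items


def test_subsample_is_deterministic_under_seed():
    items = list(range(100))
    assert subsample(items, 10, seed=42) == subsample(items, 10, seed=42)
    assert subsample(items, 10, seed=42) != subsample(items, 10, seed=43)


def test_subsample_negative_n_rejected():
    with pytest.raises(ValidationError):
        subsample([1, 2, 3], -1, seed=0)


def test_subsample_uniformity_one_of_three():
    """Selection frequency of each item is ~1/3 over many seeded draws."""
    counts = {0: 0, 1: 0, 2: 0}
    n_draws = 10_000
    for seed in range(n_draws):
        (chosen,) = subsample([0, 1, 2], 1, seed=seed)
        counts[chosen] += 1
    for item in counts:
        assert abs(counts[item] / n_draws - 1 / 3) < 0.02


# --- method overlap ---------------------------------------------------------


def test_overlap_union_denominator():
    rec = method_overlap({"x", "y"}, {"y", "z"})
    assert (rec.n_shared, rec.n_a_only, rec.n_b_only) == (1, 1, 1)
    assert rec.shared_pct == 33.33


def test_overlap_identical_and_disjoint():
    assert method_overlap({"a"}, {"a"}).shared_pct == 100.00
    assert method_overlap({"a"}, {"b"}).shared_pct == 0.00


def test_overlap_of_two_empty_sets_is_an_error():
    with pytest.raises(ValidationError):
        method_overlap(set(), set())


def test_coarsening_rank_never_decreases_shared_pct():
    """Species-level sets that disagree can only agree more at genus level
    when every member has a genus."""
    genus = ["Bacteria", "p", "c", "o", "f"]
    species_a = [Lineage.from_labels(genus + [f"g{i}", f"g{i} spA"]) for i in range(6)]
    species_b = [Lineage.from_labels(genus + [f"g{i}", f"g{i} spB"]) for i in range(6)]
    from phylofilt import genus_or_fallback_set, phylotype_label

    sp_a = {phylotype_label(lin).label for lin in species_a}
    sp_b = {phylotype_label(lin).label for lin in species_b}
    ge_a = genus_or_fallback_set(species_a)
    ge_b = genus_or_fallback_set(species_b)
    assert method_overlap(ge_a, ge_b).shared_pct >= method_overlap(sp_a, sp_b).shared_pct
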