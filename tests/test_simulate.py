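"""Determinism and statistical structure of the mock-community generators."""

import io
import math

import numpy as np
import pytest

from phylofilt import (
    CommunitySpec,
    MetagenomeSpec,
    NoiseSpec,
    QcParams,
    ValidationError,
    annotate,
    parse_blast_tabular,
    parse_fastq,
    phylotype_label,
    qc_fastq,
    sample_community,
    simulate_fastq,
    simulate_metagenome_hits,
    simulate_otu_tables,
    superkingdom_profile,
    top_hit_per_query,
)


def test_empty_community():
    assert len(sample_community(CommunitySpec(n_taxa=0, seed=1))) == 0


def test_abundances_normalised():
    c = sample_community(CommunitySpec(n_taxa=40, seed=3))
    assert math.isclose(c.abundances.sum(), 1.0, abs_tol=1e-12)


def test_same_seed_same_community():
    a = sample_community(CommunitySpec(n_taxa=25, seed=11))
    b = sample_community(CommunitySpec(n_taxa=25, seed=11))
    assert a.lineages == b.lineages
    assert np.array_equal(a.abundances, b.abundances)


def test_noise_free_tables_match_true_support():
    c = sample_community(CommunitySpec(n_taxa=30, seed=5))
    table, truth = simulate_otu_tables(
        c, NoiseSpec(depth=5000, spurious_otu_rate=0.0, contaminants=(), seed=5)
    )
    assert set(table.otu_ids) == set(truth.true_otu_ids)
    assert truth.artefact_otu_ids == []


def test_artefacts_are_count_one_in_one_replicate():
    c = sample_community(CommunitySpec(n_taxa=30, seed=7))
    table, truth = simulate_otu_tables(c, NoiseSpec(depth=5000, seed=7))
    assert truth.artefact_otu_ids
    for oid in truth.artefact_otu_ids:
        row = table.counts.loc[oid]
        assert row.sum() == 1 and (row > 0).sum() == 1


def test_contaminants_spiked_at_configured_counts():
    c = sample_community(CommunitySpec(n_taxa=10, seed=9))
    spikes = (("Eukaryota;Streptophyta;M;F;Fab;Cicer;Cicer arietinum", 1),
              ("Eukaryota;Streptophyta;M;S;Sol;Nicotiana;Nicotiana sylvestris", 15))
    table, truth = simulate_otu_tables(
        c, NoiseSpec(depth=2000, spurious_otu_rate=0, contaminants=spikes, seed=9)
    )
    assert [table.counts.loc[o].sum() for o in truth.contaminant_otu_ids] == [1, 15]


def test_zero_depth_with_artefacts_rejected():
    with pytest.raises(ValidationError):
        NoiseSpec(depth=0, spurious_otu_rate=0.01)


def test_multinomial_proportions_track_true_abundances():
    """At depth 10^4 the per-replicate count fractions of true taxa sit
    within 3 standard errors of the true relative abundances."""
    c = sample_community(CommunitySpec(n_taxa=20, lognormal_sigma=1.0, seed=13))
    table, truth = simulate_otu_tables(
        c, NoiseSpec(depth=10_000, spurious_otu_rate=0, contaminants=(), seed=13)
    )
    depth = 10_000
    n_beyond_3se = 0
    for i, oid in enumerate(truth.true_otu_ids):
        p = c.abundances[i]
        se = math.sqrt(p * (1 - p) / depth)
        for rep in table.replicate_ids:
            observed = table.counts.loc[oid, rep] / depth
            # a rare >3-SE cell is expected among 60 draws; >5 SE is not
            assert abs(observed - p) <= 5 * se + 2 / depth
            if abs(observed - p) > 3 * se + 2 / depth:
                n_beyond_3se += 1
    assert n_beyond_3se <= 2


def test_metagenome_profile_tracks_mixture():
    c = sample_community(CommunitySpec(n_taxa=30, seed=17))
    spec = MetagenomeSpec(
        n_queries=10_000, mixture=(("Bacteria", 0.6), ("unknown", 0.4)), seed=17
    )
    text, taxmap, _truth = simulate_metagenome_hits(c, spec)
    gated = parse_blast_tabular(io.StringIO(text))
    profile = superkingdom_profile(annotate(top_hit_per_query(gated.hits), taxmap))
    assert abs(profile["Bacteria"] - 60.0) < 2.0
    assert abs(profile["unknown"] - 40.0) < 2.0


def test_overlap_fraction_zero_shares_no_genus():
    c = sample_community(CommunitySpec(n_taxa=40, seed=19))
    spec = MetagenomeSpec(
        n_queries=300, mixture=(("Bacteria", 1.0),), overlap_fraction=0.0, seed=19
    )
    _text, taxmap, _ = simulate_metagenome_hits(c, spec)
    meta_genera = {
        lin.label_at("genus")
        for lin in taxmap.lineages.values()
        if lin.label_at("genus")
    }
    assert meta_genera.isdisjoint(c.genera("Bacteria"))


def test_overlap_fraction_one_draws_every_bacterial_genus_from_community():
    c = sample_community(CommunitySpec(n_taxa=40, seed=23))
    spec = MetagenomeSpec(
        n_queries=300, mixture=(("Bacteria", 1.0),), overlap_fraction=1.0,
        max_hits_per_query=1, seed=23
    )
    _text, taxmap, truth = simulate_metagenome_hits(c, spec)
    community_genera = c.genera("Bacteria")
    for sid, lin in taxmap.lineages.items():
        if sid.startswith("cell"):
            assert lin.label_at("genus") in community_genera


def test_fastq_boundary_probabilities():
    all_good = simulate_fastq(20, 50, 1.0, seed=1)
    kept, _ = qc_fastq(parse_fastq(io.StringIO(all_good)), QcParams(trim_head=0, trim_tail=0))
    assert len(kept) == 20
    all_bad = simulate_fastq(20, 50, 0.0, seed=1)
    kept, _ = qc_fastq(parse_fastq(io.StringIO(all_bad)), QcParams(trim_head=0, trim_tail=0))
    assert kept == []


def test_generators_bit_reproducible_under_seed():
    c = sample_community(CommunitySpec(n_taxa=15, seed=29))
    t1, _ = simulate_otu_tables(c, NoiseSpec(depth=1000, seed=31))
    t2, _ = simulate_otu_tables(c, NoiseSpec(depth=1000, seed=31))
    assert t1.counts.equals(t2.counts)
    h1, _, _ = simulate_metagenome_hits(c, MetagenomeSpec(n_queries=50, seed=37))
    h2, _, _ = simulate_metagenome_hits(c, MetagenomeSpec(n_queries=50, seed=37))
    assert h1 == h2
    assert simulate_fastq(10, 30, 0.9, 41) == simulate_fastq(10, 30, 0.9, 41)


def test_t1_recovers_true_community_exactly():
    """Per-replicate singleton removal strips artefacts and count-1
    contaminant spikes, leaving exactly the true phylotype set."""
    from phylofilt import aggregate_to_phylotypes, remove_singletons

    c = sample_community(CommunitySpec(n_taxa=40, seed=43))
    table, truth = simulate_otu_tables(c, NoiseSpec(depth=8000, seed=47))
    cleaned = aggregate_to_phylotypes(remove_singletons(table))
    expected = set(truth.true_phylotypes)
    for oid, spike in truth.contaminant_spikes.items():
        if spike > 1:
            expected.add(phylotype_label(table.taxonomy[oid]))
    assert cleaned.labels == expected
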