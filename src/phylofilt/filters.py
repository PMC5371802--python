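"""The stringency cascade: replicate-aware singleton removal and
minimum-copy filters, with retention reporting.

Five levels are used in a triplicate-PCR amplicon design:

========  =============================================================
T0        no filter (any nonzero count)
T1        count-1 cells zeroed independently per replicate, at OTU level
T10       >= 10 copies of a phylotype in at least one replicate
T10-R1    >= 10 copies in at least two replicates
T10-R2    >= 10 copies in every replicate
========  =============================================================

Singleton removal acts below phylotype level (on OTU cells) and the table
is re-aggregated afterwards, so OTU counts drop under T1 as well.  The
T10-family thresholds are evaluated on raw phylotype counts.  The surviving
phylotype sets nest: T10-R2 ⊆ T10-R1 ⊆ T10 ⊆ T1 ⊆ T0, because any
phylotype reaching 10 copies in a replicate survives singleton zeroing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import (
    FilterReport,
    LevelStats,
    OtuTable,
    PhylotypeLabel,
    PhylotypeTable,
    StringencyLevel,
    ValidationError,
    VennPartition,
    round_half_away as _round_half_away,
    standard_levels,
    venn_partition,
)
from .phylotypes import aggregate_to_phylotypes

__all__ = [
    "remove_singletons",
    "apply_stringency",
    "run_cascade",
    "CascadeResult",
    "retention_report",
    "retention_percent",
    "mean_replicate_retention",
    "per_replicate_retention",
    "core_across_levels",
    "per_replicate_analysis",
]


def remove_singletons(table: OtuTable) -> OtuTable:
    """Zero every count-1 cell, independently per replicate, at OTU level.

    Rows left all-zero are dropped.  Exactly (number of cells equal to 1)
    units of count mass are removed.
    """
    counts = table.counts.copy()
    counts[counts == 1] = 0
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    return OtuTable(counts, {o: table.taxonomy[o] for o in counts.index})


def _keep_mask(ptable: PhylotypeTable, level: StringencyLevel):
    return (ptable.counts >= level.min_count).sum(axis=1) >= level.min_replicates


def apply_stringency(
    ptable: PhylotypeTable,
    level: StringencyLevel,
    source_otus: OtuTable | None = None,
) -> PhylotypeTable:
    """Filter a phylotype table at one stringency level.

    Singleton-removing levels (T1) require ``source_otus`` — the OTU table
    the phylotypes were aggregated from — because the count-1 zeroing acts
    below phylotype level.  Threshold levels are evaluated on the raw
    phylotype counts.
    """
    n_reps = len(ptable.replicate_ids)
    if level.min_replicates > n_reps:
        raise ValidationError(
            f"{level.name}: min_replicates={level.min_replicates} exceeds the "
            f"{n_reps} replicate(s) present"
        )
    if level.remove_singletons:
        if source_otus is None:
            raise ValidationError(f"{level.name} needs the source OTU table")
        ptable = aggregate_to_phylotypes(remove_singletons(source_otus))
    mask = _keep_mask(ptable, level)
    kept = ptable.counts[mask]
    labels = list(kept.index)
    return PhylotypeTable(
        kept.copy(),
        lineages={p: ptable.lineages[p] for p in labels},
        members={p: ptable.members.get(p, frozenset()) for p in labels},
    )


@dataclass
class CascadeResult:
    """Filtered OTU and phylotype tables for every level of the cascade."""

    otu_tables: dict[str, OtuTable]
    phylotype_tables: dict[str, PhylotypeTable]
    levels: dict[str, StringencyLevel] = field(default_factory=dict)

    def phylotype_sets(self) -> dict[str, set[PhylotypeLabel]]:
        return {name: t.labels for name, t in self.phylotype_tables.items()}


def run_cascade(
    otus: OtuTable, levels: Mapping[str, StringencyLevel] | None = None
) -> CascadeResult:
    """Apply every stringency level to one OTU table.

    For each level the surviving phylotype table is computed, together with
    the OTU table restricted to the member OTUs of surviving phylotypes
    (after singleton zeroing, for T1), so OTU-level retention can be
    reported alongside phylotype-level retention.
    """
    levels = dict(levels) if levels is not None else standard_levels(otus.n_replicates)
    baseline = aggregate_to_phylotypes(otus)
    otu_tables: dict[str, OtuTable] = {}
    ptables: dict[str, PhylotypeTable] = {}
    for name, level in levels.items():
        source = remove_singletons(otus) if level.remove_singletons else otus
        ptab = apply_stringency(baseline, level, source_otus=otus)
        ptables[name] = ptab
        otu_tables[name] = source.select(ptab.member_otu_ids())
    return CascadeResult(otu_tables, ptables, levels)


def retention_percent(baseline: int, filtered: int, ndigits: int = 2) -> float:
    """Percentage retained versus a baseline, rounded half away from zero."""
    if baseline <= 0:
        raise ValidationError("baseline count must be positive")
    return _round_half_away(100.0 * filtered / baseline, ndigits)


def retention_report(cascade: CascadeResult, baseline: str = "T0") -> FilterReport:
    """Phylotype/OTU/read retention for every level versus the baseline.

    Percentages are rounded to two decimals; the baseline row is 100.00 by
    construction.
    """
    if baseline not in cascade.phylotype_tables:
        raise ValidationError(f"baseline level {baseline!r} missing from the cascade")
    base_p = cascade.phylotype_tables[baseline]
    base_reads = base_p.total_counts
    if len(base_p) == 0 or base_reads == 0:
        raise ValidationError("baseline table is empty")
    stats: dict[str, LevelStats] = {}
    for name, ptab in cascade.phylotype_tables.items():
        stats[name] = LevelStats(
            phylotype_count=len(ptab),
            otu_count=len(cascade.otu_tables[name]),
            read_total=ptab.total_counts,
            pct_phylotypes_retained=retention_percent(len(base_p), len(ptab)),
            pct_reads_retained=retention_percent(base_reads, ptab.total_counts),
        )
    return FilterReport(stats, baseline=baseline)


def _single_replicate_level(level: StringencyLevel) -> StringencyLevel:
    return StringencyLevel(level.name, level.min_count, 1, level.remove_singletons)


def per_replicate_retention(
    otus: OtuTable, level: StringencyLevel
) -> tuple[dict[str, tuple[int, int, float]], int]:
    """Phylotype retention of ``level`` within each replicate separately.

    Returns per replicate (baseline phylotypes, surviving phylotypes, pct)
    plus the mean percentage across replicates rounded to the nearest whole
    percent (half away from zero) — the "on average 65%" style figure.
    """
    rule = _single_replicate_level(level)
    out: dict[str, tuple[int, int, float]] = {}
    fractions = []
    for rep in otus.replicate_ids:
        sub = otus.single_replicate(rep)
        base = aggregate_to_phylotypes(sub)
        kept = apply_stringency(base, rule, source_otus=sub)
        pct = retention_percent(len(base), len(kept)) if len(base) else 0.0
        out[rep] = (len(base), len(kept), pct)
        if len(base):
            fractions.append(100.0 * len(kept) / len(base))
    mean_pct = int(_round_half_away(sum(fractions) / len(fractions))) if fractions else 0
    return out, mean_pct


def mean_replicate_retention(pairs: Sequence[tuple[int, int]]) -> int:
    """Mean of per-replicate retention percentages (baseline, filtered),
    rounded to the nearest whole percent, half away from zero."""
    if not pairs:
        raise ValidationError("no replicate pairs supplied")
    fractions = []
    for base, kept in pairs:
        if base <= 0:
            raise ValidationError("baseline count must be positive")
        fractions.append(100.0 * kept / base)
    return int(_round_half_away(sum(fractions) / len(fractions)))


def core_across_levels(
    level_sets: Mapping[str, Iterable[PhylotypeLabel]]
) -> set[PhylotypeLabel]:
    """Phylotypes common to every supplied stringency level.

    Under the nesting property this equals the most stringent level's set,
    but the intersection is computed explicitly so non-nested inputs (e.g.
    per-replicate sets) are handled too.
    """
    if len(level_sets) < 2:
        raise ValidationError("need at least two levels to intersect")
    sets = [set(s) for s in level_sets.values()]
    core = sets[0]
    for s in sets[1:]:
        core = core & s
    return core


def per_replicate_analysis(
    otus: OtuTable, level: StringencyLevel
) -> tuple[dict[str, set[PhylotypeLabel]], VennPartition]:
    """Apply a level within each replicate and compare the surviving sets.

    ``min_replicates`` is forced to 1 inside a single replicate.  Returns
    the per-replicate phylotype sets and their Venn partition.
    """
    rule = _single_replicate_level(level)
    sets: dict[str, set[PhylotypeLabel]] = {}
    for rep in otus.replicate_ids:
        sub = otus.single_replicate(rep)
        base = aggregate_to_phylotypes(sub)
        kept = apply_stringency(base, rule, source_otus=sub)
        sets[rep] = kept.labels
    return sets, venn_partition(sets)
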