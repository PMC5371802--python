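"""Presence–absence comparison between size fractions.

Compares the genus content of the <0.45 µm metagenome annotations against
the >0.45 µm prokaryote and eukaryote amplicon communities at each
stringency level.  All three label sets are projected to genus — or, when
no genus is assigned, to the most specific assigned rank (genus-or-
fallback) — and intersected with a generic Venn engine.  The metagenome
set is held at its unfiltered annotation while the amplicon stringency
varies, so only the amplicon-side sets shrink as the level rises.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .annotate import AnnotationSet, OverlapRecord, method_overlap
from .model import (
    OtuTable,
    PhylotypeTable,
    RANKS_SILVA,
    StringencyLevel,
    UNKNOWN_LABEL,
    VennPartition,
    venn_partition,
)
from .phylotypes import aggregate_to_phylotypes, project_to_rank
from .filters import apply_stringency

logger = logging.getLogger(__name__)

__all__ = ["FractionReport", "genus_or_fallback_set", "compare_fractions", "venn_partition"]


@dataclass
class FractionReport:
    """Genus-or-fallback overlap between the three datasets at one level."""

    level: StringencyLevel
    metagenome: set[str]
    prokaryote: set[str]
    eukaryote: set[str]
    venn: VennPartition
    pairwise: dict[tuple[str, str], OverlapRecord]


def genus_or_fallback_set(
    lineages,
    rank: str = "genus",
    rank_order: tuple[str, ...] = RANKS_SILVA,
    include_unknown: bool = False,
) -> set[str]:
    """Project an iterable of lineages to rank-or-fallback labels.

    Unassigned lineages are excluded by default: a shared "unknown" token
    would register as a spurious common taxon between datasets.
    """
    out: set[str] = set()
    for lineage in lineages:
        proj = project_to_rank(lineage, rank, rank_order)
        if proj.label == UNKNOWN_LABEL and proj.rank is None and not include_unknown:
            continue
        out.add(proj.label)
    return out


def compare_fractions(
    meta: AnnotationSet,
    prok_otus: OtuTable,
    euk_otus: OtuTable,
    level: StringencyLevel,
    rank: str = "genus",
    rank_order: tuple[str, ...] = RANKS_SILVA,
) -> FractionReport:
    """Presence–absence comparison of metagenome vs amplicon fractions.

    The amplicon OTU tables are aggregated to phylotypes and filtered at
    ``level``; the metagenome annotation set is used as-is (its own
    stringency is fixed at no-filter).  All sets are projected through
    rank-or-fallback before the Venn partition and pairwise shared
    percentages (union denominator) are computed.
    """
    meta_set = genus_or_fallback_set(meta.lineages().values(), rank, rank_order)

    amplicon_sets: dict[str, set[str]] = {}
    for name, otus in (("prokaryote", prok_otus), ("eukaryote", euk_otus)):
        ptab = apply_stringency(aggregate_to_phylotypes(otus), level, source_otus=otus)
        if len(ptab) == 0:
            warnings.warn(
                f"{name} amplicon set is empty after {level.name}; regions will be zeroed",
                stacklevel=2,
            )
        amplicon_sets[name] = genus_or_fallback_set(
            ptab.lineages.values(), rank, rank_order
        )

    named = {
        "metagenome": meta_set,
        "prokaryote": amplicon_sets["prokaryote"],
        "eukaryote": amplicon_sets["eukaryote"],
    }
    venn = venn_partition(named)
    pairwise: dict[tuple[str, str], OverlapRecord] = {}
    names = list(named)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if named[a] or named[b]:
                pairwise[(a, b)] = method_overlap(named[a], named[b])
            else:
                pairwise[(a, b)] = OverlapRecord(0, 0, 0, 0.0)
    return FractionReport(
        level=level,
        metagenome=meta_set,
        prokaryote=named["prokaryote"],
        eukaryote=named["eukaryote"],
        venn=venn,
        pairwise=pairwise,
    )
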