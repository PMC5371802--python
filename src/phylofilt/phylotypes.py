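"""Collapsing OTUs into phylotypes and projecting lineages across ranks.

A *phylotype* is defined operationally as the most specific (lowest)
assigned taxon label of an OTU's lineage: OTUs whose lineages bottom out at
the same (rank, label) pair merge into one phylotype, whatever happens
above or below that rank.  An empty lineage maps to the reserved "unknown"
phylotype.  Labels are compared case-sensitively after whitespace
normalisation; homonyms at different ranks stay distinct because the
(rank, label) pair is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import (
    RANKS_SILVA,
    UNKNOWN_LABEL,
    Lineage,
    OtuTable,
    PhylotypeLabel,
    PhylotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["phylotype_label", "aggregate_to_phylotypes", "project_to_rank", "RankProjection"]


def _normalise(label: str) -> str:
    return " ".join(label.split())


def phylotype_label(lineage: Lineage) -> PhylotypeLabel:
    """The most specific assigned (rank, label) pair of a lineage.

    An empty lineage yields the unknown phylotype ``("unknown", None)``.
    """
    if lineage.is_empty:
        return PhylotypeLabel(UNKNOWN_LABEL, None)
    rank, label = lineage.lowest
    return PhylotypeLabel(_normalise(label), rank)


def aggregate_to_phylotypes(table: OtuTable) -> PhylotypeTable:
    """Merge OTUs sharing a phylotype label, summing counts per replicate.

    Count mass is conserved exactly; member OTU sets partition the input
    OTUs.  Identical labels arising from conflicting lineage paths are kept
    as one phylotype keyed by (rank, label) but the conflict is logged.
    """
    labels = {otu: phylotype_label(table.taxonomy[otu]) for otu in table.otu_ids}
    members: dict[PhylotypeLabel, list[str]] = {}
    for otu, plabel in labels.items():
        members.setdefault(plabel, []).append(otu)

    lineages: dict[PhylotypeLabel, Lineage] = {}
    for plabel, otus in members.items():
        lins = {table.taxonomy[o].ranks for o in otus}
        if len(lins) > 1:
            logger.info(
                "phylotype %r (%s) aggregates %d distinct lineage paths",
                plabel.label,
                plabel.rank,
                len(lins),
            )
        lineages[plabel] = table.taxonomy[otus[0]]

    order = list(members)
    if table.counts.empty:
        counts = pd.DataFrame(columns=table.replicate_ids, index=pd.Index([], dtype=object))
    else:
        grouped = table.counts.groupby(
            table.counts.index.map(labels.get), sort=False
        ).sum()
        counts = grouped.loc[order]
    return PhylotypeTable(
        counts,
        lineages=lineages,
        members={p: frozenset(o) for p, o in members.items()},
    )


@dataclass(frozen=True)
class RankProjection:
    """A lineage projected to a target rank, with fallback bookkeeping."""

    label: str
    rank: str | None
    is_fallback: bool


def project_to_rank(
    lineage: Lineage, rank: str, rank_order: tuple[str, ...] = RANKS_SILVA
) -> RankProjection:
    """The label at ``rank``, else the most specific assigned label.

    Used for genus-or-fallback comparisons: a lineage assigned only to
    family projects to that family label flagged as a fallback; an empty
    lineage projects to "unknown".
    """
    if rank not in rank_order:
        raise ValidationError(f"rank {rank!r} not in the configured rank order")
    if lineage.is_empty:
        return RankProjection(UNKNOWN_LABEL, None, False)
    at_rank = lineage.label_at(rank)
    if at_rank is not None:
        return RankProjection(_normalise(at_rank), rank, False)
    low_rank, low_label = lineage.lowest
    return RankProjection(_normalise(low_label), low_rank, True)
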