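"""Shared domain types for the amplicon / metagenome comparison pipeline.

The central observable is the :class:`OtuTable`: integer read counts per OTU
per PCR replicate, with a ranked taxonomic lineage attached to every OTU.
Phylotypes (OTUs collapsed at their lowest assigned rank) and the stringency
levels used to filter them are defined here as well, so the filtering,
annotation and comparison modules all speak the same vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RANKS_SILVA",
    "RANKS_ICTV",
    "UNKNOWN_LABEL",
    "Lineage",
    "QualityRead",
    "BlastHit",
    "StringencyLevel",
    "standard_levels",
    "OtuTable",
    "PhylotypeLabel",
    "PhylotypeTable",
    "FilterReport",
    "LevelStats",
    "VennPartition",
    "ValidationError",
    "round_half_away",
    "venn_partition",
]

#: SILVA-style rank order used for cellular (16S/18S) lineages.
RANKS_SILVA: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: ICTV-style rank order used for curated viral lineages.
RANKS_ICTV: tuple[str, ...] = (
    "superkingdom",
    "order",
    "family",
    "subfamily",
    "genus",
    "species",
)

#: Label rendered for an empty (unassigned) lineage in every report.
UNKNOWN_LABEL = "unknown"


class ValidationError(ValueError):
    """Raised when an on-disk table or a domain object violates its contract."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero — the convention behind reported
    percentages like 59.19 and replicate means like 65."""
    factor = 10**ndigits
    scaled = x * factor
    return math.floor(scaled + 0.5) / factor if scaled >= 0 else math.ceil(scaled - 0.5) / factor


@dataclass(frozen=True)
class Lineage:
    """A ranked taxonomy path from most general to most specific.

    ``ranks`` is an ordered tuple of ``(rank_name, taxon_label)`` pairs.  An
    empty tuple means the taxon is unassigned ("unknown").  Truncation is only
    allowed at the tail: every assigned label must be non-empty.
    """

    ranks: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for rank, label in self.ranks:
            if not label:
                raise ValidationError(
                    f"empty taxon label at rank {rank!r}; truncate at the tail instead"
                )

    @classmethod
    def from_labels(
        cls, labels: Sequence[str], rank_order: Sequence[str] = RANKS_SILVA
    ) -> "Lineage":
        """Build a lineage by zipping labels onto a rank order, e.g. from a
        semicolon-joined SILVA string split on ';'."""
        labels = [lab.strip() for lab in labels]
        # drop trailing empties (truncated lineages)
        while labels and not labels[-1]:
            labels.pop()
        if len(labels) > len(rank_order):
            raise ValidationError(
                f"{len(labels)} labels exceed the {len(rank_order)}-rank order"
            )
        return cls(tuple(zip(rank_order[: len(labels)], labels)))

    @classmethod
    def from_string(
        cls, text: str, rank_order: Sequence[str] = RANKS_SILVA, sep: str = ";"
    ) -> "Lineage":
        text = text.strip()
        if not text or text.lower() == UNKNOWN_LABEL:
            return cls()
        return cls.from_labels(text.split(sep), rank_order)

    def to_string(self, sep: str = ";") -> str:
        return sep.join(label for _, label in self.ranks)

    @property
    def is_empty(self) -> bool:
        return not self.ranks

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, label in self.ranks)

    def label_at(self, rank: str) -> str | None:
        """The label assigned at ``rank``, or None if the lineage is truncated
        above it (or does not use that rank)."""
        for r, label in self.ranks:
            if r == rank:
                return label
        return None

    @property
    def lowest(self) -> tuple[str, str] | None:
        """The most specific assigned ``(rank, label)`` pair, or None."""
        return self.ranks[-1] if self.ranks else None

    def truncated(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth])

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.to_string() if self.ranks else UNKNOWN_LABEL


@dataclass
class QualityRead:
    """One sequencing read with per-base Phred quality scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValidationError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValidationError(f"read {self.id!r}: Phred score outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BlastHit:
    """One record of the 12-column BLAST tabular (outfmt 6) dialect.

    Coordinates are kept 1-based inclusive, as BLAST emits them.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if not math.isfinite(self.bit_score):
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: non-finite bit-score")
        if min(self.q_start, self.q_end, self.s_start, self.s_end) < 1:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: coordinates must be >= 1 (1-based)"
            )


@dataclass(frozen=True)
class StringencyLevel:
    """A replicate-aware abundance filter.

    ``min_count`` copies of a phylotype must be present in at least
    ``min_replicates`` replicates; ``remove_singletons`` additionally zeroes
    count-1 cells per replicate at the OTU level before aggregation.

    The named presets of the three-replicate study design are::

        T0     = (1, 1, no singleton removal)   -- no filter
        T1     = (1, 1, singleton removal)
        T10    = (10, 1, no)
        T10-R1 = (10, 2, no)
        T10-R2 = (10, R, no)    with R = number of replicates
    """

    name: str
    min_count: int = 1
    min_replicates: int = 1
    remove_singletons: bool = False

    def __post_init__(self) -> None:
        if self.min_count < 1 or self.min_replicates < 1:
            raise ValidationError("min_count and min_replicates must be >= 1")

    @classmethod
    def from_name(cls, name: str, n_replicates: int = 3) -> "StringencyLevel":
        key = name.upper().replace("-", "_")
        presets = {
            "T0": cls("T0", 1, 1, False),
            "T1": cls("T1", 1, 1, True),
            "T10": cls("T10", 10, 1, False),
            "T10_R1": cls("T10-R1", 10, 2, False),
            "T10_R2": cls("T10-R2", 10, n_replicates, False),
        }
        if key not in presets:
            raise ValidationError(
                f"unknown stringency level {name!r}; expected one of {sorted(presets)}"
            )
        return presets[key]


def standard_levels(n_replicates: int = 3) -> dict[str, StringencyLevel]:
    """The study's full cascade, ordered from least to most stringent."""
    names = ["T0", "T1", "T10", "T10-R1", "T10-R2"]
    return {n: StringencyLevel.from_name(n, n_replicates) for n in names}


def _validate_counts(counts: pd.DataFrame, what: str) -> pd.DataFrame:
    if counts.columns.duplicated().any():
        raise ValidationError(f"{what}: duplicate replicate names")
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].tolist()
        raise ValidationError(f"{what}: duplicate row ids {dups[:5]}")
    try:
        counts = counts.astype("int64")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{what}: non-integer count ({exc})") from exc
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)].tolist()
        raise ValidationError(f"{what}: negative counts in rows {bad[:5]}")
    return counts


@dataclass
class OtuTable:
    """Per-replicate integer read counts per OTU, with taxonomy.

    ``counts`` is a DataFrame indexed by OTU id with one integer column per
    replicate.  Every OTU has a :class:`Lineage` in ``taxonomy`` (possibly the
    empty lineage when the assignment is unknown).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, Lineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = _validate_counts(self.counts, "OTU table")
        for otu in self.counts.index:
            self.taxonomy.setdefault(otu, Lineage())

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total_counts(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __len__(self) -> int:
        return self.counts.shape[0]

    def select(self, otu_ids: Iterable[str]) -> "OtuTable":
        ids = [i for i in self.counts.index if i in set(otu_ids)]
        return OtuTable(
            self.counts.loc[ids].copy(),
            {i: self.taxonomy[i] for i in ids},
        )

    def single_replicate(self, replicate: str) -> "OtuTable":
        """The table restricted to one replicate, zero rows dropped."""
        sub = self.counts[[replicate]]
        sub = sub[sub[replicate] > 0]
        return OtuTable(sub.copy(), {i: self.taxonomy[i] for i in sub.index})


@dataclass(frozen=True, order=True)
class PhylotypeLabel:
    """A phylotype: the most specific assigned taxon of a lineage.

    ``rank`` is None for the unknown phylotype.  Homonymous labels at
    different ranks stay distinct because the pair is the identity.
    """

    label: str
    rank: str | None = None

    def __str__(self) -> str:
        return self.label


@dataclass
class PhylotypeTable:
    """Counts aggregated at phylotype level.

    Same shape as :class:`OtuTable` but keyed by :class:`PhylotypeLabel`;
    every phylotype carries its lineage and the set of member OTU ids.
    """

    counts: pd.DataFrame  # index: PhylotypeLabel objects
    lineages: dict[PhylotypeLabel, Lineage] = field(default_factory=dict)
    members: dict[PhylotypeLabel, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = _validate_counts(self.counts, "phylotype table")

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def labels(self) -> set[PhylotypeLabel]:
        return set(self.counts.index)

    @property
    def total_counts(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __len__(self) -> int:
        return self.counts.shape[0]

    def member_otu_ids(self) -> set[str]:
        out: set[str] = set()
        for m in self.members.values():
            out |= m
        return out


@dataclass
class LevelStats:
    """Retention bookkeeping for one stringency level."""

    phylotype_count: int
    otu_count: int
    read_total: int
    pct_phylotypes_retained: float
    pct_reads_retained: float


@dataclass
class FilterReport:
    """Phylotype / read retention across the stringency cascade.

    Percentages are relative to the T0 (unfiltered) baseline, rounded to two
    decimals; the baseline itself is 100.00 by construction.
    """

    levels: dict[str, LevelStats]
    baseline: str = "T0"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {
                    "phylotypes": s.phylotype_count,
                    "otus": s.otu_count,
                    "reads": s.read_total,
                    "pct_phylotypes": s.pct_phylotypes_retained,
                    "pct_reads": s.pct_reads_retained,
                }
                for name, s in self.levels.items()
            }
        ).T


@dataclass
class VennPartition:
    """Disjoint region decomposition of named sets.

    ``regions`` maps a frozenset of set names (the sets a member belongs to)
    to the sorted member list of that exclusive region.  Region cardinalities
    therefore sum to the size of the union.
    """

    set_names: tuple[str, ...]
    regions: dict[frozenset[str], list]

    @property
    def region_sizes(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def size(self, *names: str) -> int:
        """Cardinality of the exclusive region belonging to exactly ``names``."""
        return len(self.regions.get(frozenset(names), []))


def venn_partition(named_sets: Mapping[str, Iterable]) -> VennPartition:
    """Partition the union of named sets into disjoint membership regions."""
    names = list(named_sets)
    if len(names) != len(set(names)):
        raise ValidationError("duplicate set names in Venn input")
    if len(names) < 2:
        raise ValidationError("need at least two named sets")
    sets = {n: set(s) for n, s in named_sets.items()}
    regions: dict[frozenset[str], list] = {}
    union = set().union(*sets.values())
    for member in union:
        key = frozenset(n for n in names if member in sets[n])
        regions.setdefault(key, []).append(member)
    for key in regions:
        regions[key] = sorted(regions[key], key=repr)
    return VennPartition(tuple(names), regions)
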