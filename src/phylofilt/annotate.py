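"""Top-hit taxonomy assignment from BLAST tabular output.

Each query is assigned the lineage of its best-scoring subject (maximal
bit-score; ties broken by minimal e-value, then input order).  Subjects
missing from the taxonomy map are kept but flagged "unknown" — mirroring
the large unknown slices typical of marine metagenome annotation — and
queries with no gated hit at all are listed as unannotated.  The same
machinery serves both a cellular (RefSeq-style) and a curated viral
(ICTV-style) taxonomy map.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TypeVar

from .model import BlastHit, Lineage, UNKNOWN_LABEL, ValidationError, round_half_away

T = TypeVar("T")

__all__ = [
    "TaxonomyMap",
    "AnnotationSet",
    "top_hit_per_query",
    "annotate",
    "superkingdom_profile",
    "subsample",
    "method_overlap",
    "OverlapRecord",
]

#: Canonical top-level categories reported in superkingdom profiles.
SUPERKINGDOMS = ("Bacteria", "Archaea", "Eukaryota", "Viruses", UNKNOWN_LABEL)


@dataclass
class TaxonomyMap:
    """Subject-id → lineage mapping with a provenance tag."""

    lineages: dict[str, Lineage]
    source: str = "refseq"

    def __post_init__(self) -> None:
        # dict keys are unique by construction; the invariant worth guarding
        # is accidental None / empty keys
        if any(not k for k in self.lineages):
            raise ValidationError("taxonomy map contains an empty subject id")

    def get(self, subject_id: str) -> Lineage | None:
        return self.lineages.get(subject_id)

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass
class AnnotationSet:
    """Per-query taxonomy assignments derived from top hits.

    ``assignments`` maps query-id → (lineage, best hit); queries whose
    subject was absent from the taxonomy map carry the empty lineage and
    are counted in ``n_unknown_subject``.  Queries with no hit are listed
    in ``unannotated``.
    """

    assignments: dict[str, tuple[Lineage, BlastHit]] = field(default_factory=dict)
    unannotated: list[str] = field(default_factory=list)
    n_unknown_subject: int = 0
    n_tie_ambiguities: int = 0

    def lineage_of(self, query_id: str) -> Lineage | None:
        entry = self.assignments.get(query_id)
        return entry[0] if entry else None

    def lineages(self) -> dict[str, Lineage]:
        return {q: lin for q, (lin, _) in self.assignments.items()}

    def __len__(self) -> int:
        return len(self.assignments)


def top_hit_per_query(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """Select the single best hit per query from e-value-gated hits.

    Best = maximal bit-score; ties broken by minimal e-value, then by input
    order (first seen wins).  The result preserves first-appearance order
    of queries.
    """
    best: dict[str, BlastHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
        elif hit.bit_score > cur.bit_score or (
            hit.bit_score == cur.bit_score and hit.evalue < cur.evalue
        ):
            best[hit.query_id] = hit
    return best


def annotate(
    tophits: Mapping[str, BlastHit],
    taxmap: TaxonomyMap,
    queries: Iterable[str] | None = None,
) -> AnnotationSet:
    """Assign each query the lineage of its top hit's subject.

    ``queries`` is the full query universe (defaults to the queries with a
    hit); members without any hit are recorded as unannotated rather than
    silently dropped, since "no hit" and "hit to an unknown subject" mean
    different things in a profile.
    """
    result = AnnotationSet()
    for qid, hit in tophits.items():
        lineage = taxmap.get(hit.subject_id)
        if lineage is None:
            result.assignments[qid] = (Lineage(), hit)
            result.n_unknown_subject += 1
        else:
            result.assignments[qid] = (lineage, hit)
    if queries is not None:
        result.unannotated = [q for q in queries if q not in tophits]
    return result


def superkingdom_profile(annotations: AnnotationSet) -> dict[str, float]:
    """Percentage of annotated queries per top-level taxonomic category.

    The category is the most general label of the assigned lineage; empty
    lineages (subject absent from the map) fall in "unknown".  Percentages
    are rounded to two decimals and sum to 100 within rounding.
    """
    if len(annotations) == 0:
        return {}
    tallies: dict[str, int] = {}
    for lineage, _hit in annotations.assignments.values():
        key = lineage.labels[0] if not lineage.is_empty else UNKNOWN_LABEL
        tallies[key] = tallies.get(key, 0) + 1
    total = sum(tallies.values())
    return {
        k: round_half_away(100.0 * v / total, 2)
        for k, v in sorted(tallies.items(), key=lambda kv: -kv[1])
    }


def subsample(items: Sequence[T], n: int, seed: int) -> list[T]:
    """Uniform sample of ``min(n, len(items))`` items without replacement.

    Library-size normalisation for read sets: deterministic under
    ``(items, n, seed)``; selected items keep their original relative
    order, and ``n >= len(items)`` returns everything unchanged.
    """
    if n < 0:
        raise ValidationError("subsample size must be >= 0")
    if n >= len(items):
        return list(items)
    rng = random.Random(seed)
    chosen = sorted(rng.sample(range(len(items)), n))
    return [items[i] for i in chosen]


@dataclass(frozen=True)
class OverlapRecord:
    """Presence–absence agreement between two label sets."""

    n_shared: int
    n_a_only: int
    n_b_only: int
    shared_pct: float  # 100 * |A ∩ B| / |A ∪ B|, two decimals


def method_overlap(set_a: Iterable, set_b: Iterable) -> OverlapRecord:
    """Shared fraction of two annotation label sets, union denominator.

    The union denominator is the convention under which "common across the
    two methods" is symmetric in the methods compared.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValidationError("both label sets are empty")
    inter = a & b
    return OverlapRecord(
        n_shared=len(inter),
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        shared_pct=round_half_away(100.0 * len(inter) / len(union), 2),
    )
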