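"""Greedy centroid OTU clustering at a fixed identity threshold.

This is a deliberately small, exactly-testable stand-in from the greedy
abundance-sorted centroid family of OTU heuristics, meant for synthetic
end-to-end runs; production OTU tables from dedicated clustering tools are
imported through :func:`phylofilt.io.read_otu_table` instead.

Identity between two sequences is computed from one optimal global
alignment (match +1, mismatch -1, gap -1) as the number of identical
aligned columns divided by the alignment length *including* gap columns.
Traceback ties are broken deterministically: diagonal, then up (gap in the
second sequence), then left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import OtuTable, ValidationError

__all__ = ["SeqRecord", "Cluster", "global_identity", "greedy_cluster"]

MATCH, MISMATCH, GAP = 1, -1, -1


@dataclass(frozen=True)
class SeqRecord:
    """A dereplicated sequence: id, bases, copy count and source replicate."""

    id: str
    bases: str
    abundance: int = 1
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValidationError(f"record {self.id!r}: abundance must be >= 1")


@dataclass
class Cluster:
    """One OTU: a centroid plus the members recruited to it."""

    centroid: SeqRecord
    members: list[SeqRecord] = field(default_factory=list)

    def counts_by_replicate(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.members:
            out[rec.replicate_id] = out.get(rec.replicate_id, 0) + rec.abundance
        return out


def global_identity(a: str, b: str) -> float:
    """Identity of one optimal global alignment of ``a`` and ``b``.

    Scoring: match +1, mismatch -1, gap -1; the denominator is the alignment
    length including gap columns, so ``"ACGT"`` vs ``"AGT"`` aligns over 4
    columns with 3 matches and scores 0.75.
    """
    if not a or not b:
        raise ValidationError("global_identity requires non-empty sequences")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    score[0, :] = np.arange(m + 1) * GAP
    score[:, 0] = np.arange(n + 1) * GAP
    amat = np.frombuffer(a.encode(), dtype=np.uint8)
    bmat = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(amat[:, None] == bmat[None, :], MATCH, MISMATCH)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        row = score[i]
        prev = row[0]
        for j in range(1, m + 1):
            best = diag[j - 1]
            if up[j - 1] > best:
                best = up[j - 1]
            left = prev + GAP
            if left > best:
                best = left
            row[j] = prev = best
    # traceback with the documented tie-break: diagonal > up > left
    i, j = n, m
    matches = 0
    length = 0
    while i > 0 or j > 0:
        length += 1
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
    return matches / length


def greedy_cluster(
    records: list[SeqRecord], threshold: float = 0.97
) -> tuple[list[Cluster], OtuTable]:
    """Abundance-sorted greedy centroid clustering.

    Records are processed in decreasing abundance (ties by id,
    lexicographic); each joins the first existing centroid — in founding
    order — with identity >= ``threshold``, otherwise it founds a new
    cluster.  The emitted :class:`OtuTable` is keyed by centroid id with one
    column per replicate observed in the input (sorted).
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    if not records:
        raise ValidationError("no records to cluster")
    ordered = sorted(records, key=lambda r: (-r.abundance, r.id))
    clusters: list[Cluster] = []
    for rec in ordered:
        for cluster in clusters:
            if global_identity(rec.bases, cluster.centroid.bases) >= threshold:
                cluster.members.append(rec)
                break
        else:
            clusters.append(Cluster(centroid=rec, members=[rec]))

    replicates = sorted({r.replicate_id for r in records})
    rows = {}
    for cluster in clusters:
        by_rep = cluster.counts_by_replicate()
        rows[cluster.centroid.id] = [by_rep.get(r, 0) for r in replicates]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=replicates)
    return clusters, OtuTable(counts)
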