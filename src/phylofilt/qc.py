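"""Read trimming and quality-retention filtering.

The rule set mirrors a common short-read amplicon QC recipe: cut a fixed
number of bases off both ends of every read (the low-quality head and tail
of 100 bp HiSeq reads), then keep only reads in which more than a given
fraction of the remaining positions reach a Phred threshold.  "More than" is
implemented strictly (0.95 exactly fails a 0.95 cut-off); the comparison is
applied after trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .model import QualityRead, ValidationError

__all__ = ["QcParams", "QcStats", "trim_read", "passes_quality", "qc_fastq"]


@dataclass(frozen=True)
class QcParams:
    """Trimming and quality-filter parameters.

    Defaults are a 10-base head/tail trim with retention of reads having
    more than 95% of positions at Q >= 20.
    """

    trim_head: int = 10
    trim_tail: int = 10
    min_fraction: float = 0.95
    q_threshold: int = 20
    min_length_after_trim: int = 1

    def __post_init__(self) -> None:
        if self.trim_head < 0 or self.trim_tail < 0:
            raise ValidationError("trim lengths must be >= 0")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValidationError("min_fraction must be in [0, 1]")


@dataclass
class QcStats:
    """Tally of filter outcomes; reads_in == kept + dropped_quality + dropped_length."""

    reads_in: int = 0
    reads_kept: int = 0
    reads_dropped_quality: int = 0
    reads_dropped_length: int = 0

    def check(self) -> None:
        if self.reads_in != (
            self.reads_kept + self.reads_dropped_quality + self.reads_dropped_length
        ):
            raise ValidationError("inconsistent QC tallies")


def trim_read(read: QualityRead, params: QcParams) -> QualityRead:
    """Cut ``trim_head`` bases from the start and ``trim_tail`` from the end.

    A read shorter than the combined trim lengths becomes empty; the caller
    tallies it as length-dropped.
    """
    stop = len(read) - params.trim_tail
    if stop <= params.trim_head:
        return QualityRead(read.id, "", [])
    return QualityRead(
        read.id,
        read.bases[params.trim_head : stop],
        read.quals[params.trim_head : stop],
    )


def passes_quality(read: QualityRead, params: QcParams) -> bool:
    """True iff strictly more than ``min_fraction`` of positions reach the
    Phred threshold.  Empty reads are a caller error (route them to the
    length tally instead)."""
    if len(read) == 0:
        raise ValidationError("passes_quality on an empty read; drop it by length first")
    n_good = sum(1 for q in read.quals if q >= params.q_threshold)
    return n_good / len(read) > params.min_fraction


def qc_fastq(
    reads: Iterable[QualityRead], params: QcParams | None = None
) -> tuple[list[QualityRead], QcStats]:
    """Trim then quality-filter a read stream, preserving order."""
    params = params or QcParams()
    stats = QcStats()
    kept: list[QualityRead] = []
    for read in reads:
        stats.reads_in += 1
        trimmed = trim_read(read, params)
        if len(trimmed) < max(params.min_length_after_trim, 1):
            stats.reads_dropped_length += 1
            continue
        if passes_quality(trimmed, params):
            kept.append(trimmed)
            stats.reads_kept += 1
        else:
            stats.reads_dropped_quality += 1
    stats.check()
    return kept, stats


def qc_stream(
    reads: Iterable[QualityRead], params: QcParams, stats: QcStats
) -> Iterator[QualityRead]:
    """Streaming variant of :func:`qc_fastq`, mutating ``stats`` in place."""
    for read in reads:
        stats.reads_in += 1
        trimmed = trim_read(read, params)
        if len(trimmed) < max(params.min_length_after_trim, 1):
            stats.reads_dropped_length += 1
            continue
        if passes_quality(trimmed, params):
            stats.reads_kept += 1
            yield trimmed
        else:
            stats.reads_dropped_quality += 1
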