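"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTQ (Phred+33, fixed — other encodings are rejected, not
guessed), tab-separated OTU/phylotype count tables, tab-separated lineage
maps (semicolon-joined ranked labels), 12-column BLAST tabular (outfmt 6)
and the Krona text-import dialect.
"""

from __future__ import annotations

import io as _io
import logging
from contextlib import contextmanager
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import (
    RANKS_SILVA,
    UNKNOWN_LABEL,
    BlastHit,
    Lineage,
    OtuTable,
    PhylotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

PHRED_OFFSET = 33

__all__ = [
    "ParseError",
    "parse_fastq",
    "write_fastq",
    "read_otu_table",
    "write_otu_table",
    "read_lineage_map",
    "write_lineage_map",
    "parse_blast_tabular",
    "BlastParseResult",
    "write_blast_tabular",
    "write_krona_text",
    "write_phylotype_table",
]


class ParseError(ValueError):
    """Raised when an input stream is syntactically malformed."""


@contextmanager
def _as_text_handle(source: str | Path | IO[str], mode: str = "r") -> Iterator[IO[str]]:
    if isinstance(source, (str, Path)):
        with open(source, mode) as fh:
            yield fh
    else:
        yield source


# ---------------------------------------------------------------------------
# FASTQ


def parse_fastq(source: str | Path | IO[str]) -> Iterator["QualityRead"]:
    """Yield reads from a 4-line-per-record Phred+33 FASTQ stream.

    Raises :class:`ParseError` on truncated records (naming the 0-based
    record index) and on base/quality length mismatches.
    """
    from .model import QualityRead

    with _as_text_handle(source) as fh:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"record {index} ({title.split()[0]}): "
                        f"{len(seq)} bases but {len(qual)} quality characters"
                    )
                quals = [ord(c) - PHRED_OFFSET for c in qual]
                if any(q < 0 or q > 60 for q in quals):
                    raise ParseError(
                        f"record {index}: quality character outside the Phred+33 "
                        "range accepted here (Q0..Q60); other encodings are rejected"
                    )
                yield QualityRead(title.split()[0], seq.upper(), quals)
                index += 1
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"truncated or malformed FASTQ at record {index}: {exc}") from exc


def write_fastq(reads: Iterable["QualityRead"], sink: str | Path | IO[str]) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _as_text_handle(sink, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# OTU tables and lineage maps


def read_lineage_map(
    source: str | Path | IO[str], rank_order: Sequence[str] = RANKS_SILVA
) -> dict[str, Lineage]:
    """Read a tab-separated ``id<TAB>semicolon-joined-lineage`` map."""
    out: dict[str, Lineage] = {}
    with _as_text_handle(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"lineage map line {lineno}: expected 2 tab-separated columns")
            key = parts[0].strip()
            if key in out:
                raise ValidationError(f"lineage map: duplicate id {key!r} at line {lineno}")
            out[key] = Lineage.from_string(parts[1], rank_order)
    return out


def write_lineage_map(taxonomy: dict[str, Lineage], sink: str | Path | IO[str]) -> None:
    with _as_text_handle(sink, "w") as fh:
        for key, lin in taxonomy.items():
            fh.write(f"{key}\t{lin.to_string() if not lin.is_empty else UNKNOWN_LABEL}\n")


def read_otu_table(
    table: str | Path | IO[str],
    taxonomy: str | Path | IO[str] | dict[str, Lineage] | None = None,
    rank_order: Sequence[str] = RANKS_SILVA,
) -> OtuTable:
    """Read a tab-separated OTU count table plus its lineage map.

    The table's header row holds replicate names and the first column the OTU
    id.  OTUs missing from the taxonomy get the empty lineage and are logged.
    Negative or non-integer counts and duplicate OTU ids raise
    :class:`~phylofilt.model.ValidationError` naming the offending row.
    """
    with _as_text_handle(table) as fh:
        frame = pd.read_csv(fh, sep="\t", header=0, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].tolist()
        raise ValidationError(f"duplicate OTU id(s): {dup[:5]}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | (numeric.fillna(0) % 1 != 0).any(axis=1)
    if bad.any():
        raise ValidationError(
            f"non-integer count in row(s): {frame.index[bad].tolist()[:5]}"
        )
    counts = numeric.astype("int64")
    if (counts.to_numpy() < 0).any():
        bad_rows = counts.index[(counts < 0).any(axis=1)].tolist()
        raise ValidationError(f"negative count in row(s): {bad_rows[:5]}")

    if taxonomy is None:
        taxmap: dict[str, Lineage] = {}
    elif isinstance(taxonomy, dict):
        taxmap = dict(taxonomy)
    else:
        taxmap = read_lineage_map(taxonomy, rank_order)
    missing = [o for o in counts.index if o not in taxmap]
    if missing:
        logger.info("%d OTU(s) missing from the taxonomy map, e.g. %s", len(missing), missing[:3])
    return OtuTable(counts, {o: taxmap.get(o, Lineage()) for o in counts.index})


def write_otu_table(
    table: OtuTable,
    table_sink: str | Path | IO[str],
    taxonomy_sink: str | Path | IO[str] | None = None,
    id_column: str = "otu_id",
) -> None:
    with _as_text_handle(table_sink, "w") as fh:
        frame = table.counts.copy()
        frame.index.name = id_column
        frame.to_csv(fh, sep="\t")
    if taxonomy_sink is not None:
        write_lineage_map(table.taxonomy, taxonomy_sink)


def write_phylotype_table(table: PhylotypeTable, sink: str | Path | IO[str]) -> None:
    """Write a phylotype table with label, rank, lineage and member columns."""
    with _as_text_handle(sink, "w") as fh:
        reps = table.replicate_ids
        fh.write("phylotype\trank\t" + "\t".join(reps) + "\tlineage\tmember_otus\n")
        for plabel in table.counts.index:
            row = table.counts.loc[plabel]
            lin = table.lineages.get(plabel, Lineage())
            members = ",".join(sorted(table.members.get(plabel, frozenset())))
            fh.write(
                f"{plabel.label}\t{plabel.rank or ''}\t"
                + "\t".join(str(int(row[r])) for r in reps)
                + f"\t{lin.to_string() if not lin.is_empty else UNKNOWN_LABEL}\t{members}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular


class BlastParseResult:
    """Hits retained under the e-value gate plus a tally of discards."""

    __slots__ = ("hits", "n_discarded")

    def __init__(self, hits: list[BlastHit], n_discarded: int) -> None:
        self.hits = hits
        self.n_discarded = n_discarded

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def parse_blast_tabular(
    source: str | Path | IO[str], max_evalue: float = 1e-5
) -> BlastParseResult:
    """Parse 12-column BLAST tabular records, gating on e-value.

    Hits with ``evalue < max_evalue`` (strict, matching an "e-values less
    than" gate) are retained; the rest are dropped and counted.
    """
    if not max_evalue > 0:
        raise ValidationError("max_evalue must be > 0")
    hits: list[BlastHit] = []
    n_discarded = 0
    with _as_text_handle(source) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hit = BlastHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    align_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if hit.evalue < max_evalue:
                hits.append(hit)
            else:
                n_discarded += 1
    return BlastParseResult(hits, n_discarded)


def write_blast_tabular(hits: Iterable[BlastHit], sink: str | Path | IO[str]) -> None:
    with _as_text_handle(sink, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.align_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.2e}",
                        f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Krona text import


def write_krona_text(entries: Iterable[tuple[int, Lineage]]) -> str:
    """Render (count, lineage) entries in the Krona text-import dialect.

    One line per entry: the count, a TAB, then the lineage labels
    TAB-separated from general to specific.  Total emitted count mass equals
    the total input mass exactly; an empty lineage is rendered as the single
    label ``unknown``.
    """
    out = _io.StringIO()
    for count, lineage in entries:
        if count < 0:
            raise ValidationError(f"negative count {count} for lineage {lineage}")
        labels = lineage.labels if not lineage.is_empty else (UNKNOWN_LABEL,)
        out.write(str(int(count)) + "\t" + "\t".join(labels) + "\n")
    return out.getvalue()
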