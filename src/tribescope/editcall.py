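"""Mismatch calling and strand-aware A>I editing-event detection.

The caller applies two filters to each pileup column: a per-read base-quality
filter (Phred strictly greater than 30, i.e. >= 31 by default) and a depth
filter on the number of quality-passing reads supporting the alternative base
(>= 2 by default). Calls at known SNP or known-editing positions are then
excluded, and the survivors are reduced to strand-aware editing events:
A>G inside plus-strand 3'UTRs, T>C inside minus-strand 3'UTRs — both read
out the same underlying A>I deamination on the transcript strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._util import logger
from .formats import PileupColumn, SiteDb, UtrAnnotation

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MismatchCall:
    contig: str
    position: int          # 1-based
    ref: str
    alt: str
    depth: int             # all non-N observations at the column
    alt_support: int       # quality-passing reads carrying alt
    min_alt_phred: int     # minimum Phred among the supporting reads

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.alt_support > self.depth:
            raise ValueError("alt_support cannot exceed depth")


@dataclass(frozen=True)
class EditingEvent:
    """A strand-aware A>I editing event assigned to a gene's 3'UTR."""

    contig: str
    position: int          # 1-based
    gene_id: str | None
    strand: str            # transcript strand
    ref: str               # A on + strand, T on - strand
    alt: str               # G on + strand, C on - strand
    depth: int
    alt_support: int


def call_mismatches(pileup: Iterable[PileupColumn], min_phred: int = 31,
                    min_alt_reads: int = 2) -> list[MismatchCall]:
    """Emit a call for every (column, alt base) with >= ``min_alt_reads``
    observations at Phred >= ``min_phred``.

    All 12 substitution classes are callable. N reference columns and N read
    bases are ignored. If two alt bases pass at one site, two calls result.
    """
    if min_phred < 0 or min_alt_reads < 1:
        raise ValueError("min_phred must be >= 0 and min_alt_reads >= 1")
    calls: list[MismatchCall] = []
    for col in pileup:
        ref = col.ref_base.upper()
        if ref not in VALID_BASES:
            continue
        depth = 0
        support: dict[str, list[int]] = {}
        for base, qual in zip(col.bases, col.quals):
            base = base.upper()
            if base not in VALID_BASES:
                continue
            depth += 1
            if base != ref and qual >= min_phred:
                support.setdefault(base, []).append(qual)
        for alt in sorted(support):
            quals = support[alt]
            if len(quals) >= min_alt_reads:
                calls.append(MismatchCall(col.contig, col.position, ref, alt,
                                          depth=depth, alt_support=len(quals),
                                          min_alt_phred=min(quals)))
    return calls


def exclude_known_sites(calls: Sequence[MismatchCall], snp_db: SiteDb | None = None,
                        editing_db: SiteDb | None = None) -> list[MismatchCall]:
    """Drop calls at positions present in either database; order preserved."""
    dbs = [db for db in (snp_db, editing_db) if db is not None]
    return [c for c in calls if not any((c.contig, c.position) in db for db in dbs)]


def editing_events(calls: Sequence[MismatchCall], annotation: UtrAnnotation,
                   restrict_to_utr: bool = True) -> list[EditingEvent]:
    """Reduce mismatch calls to strand-aware A>I events annotated with genes.

    An A>G call inside a plus-strand feature, or a T>C call inside a
    minus-strand feature, yields one event per matching feature gene
    (features of both strands at one position each get their own event).
    Calls outside any feature are dropped when ``restrict_to_utr``;
    otherwise they are kept unassigned, with strand inferred from the
    substitution itself.
    """
    events: list[EditingEvent] = []
    for call in calls:
        pair = (call.ref, call.alt)
        if pair not in (("A", "G"), ("T", "C")):
            continue
        call_strand = "+" if pair == ("A", "G") else "-"
        feats = [rec for rec in annotation.overlapping(call.contig, call.position)
                 if rec.strand == call_strand]
        if feats:
            for gene in sorted({rec.gene_id for rec in feats}):
                events.append(EditingEvent(call.contig, call.position, gene, call_strand,
                                           call.ref, call.alt, call.depth, call.alt_support))
        elif not restrict_to_utr:
            events.append(EditingEvent(call.contig, call.position, None, call_strand,
                                       call.ref, call.alt, call.depth, call.alt_support))
    return events


# ---------------------------------------------------------------------------
# TSV round-trip (VCF-like editing-event tables)
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["contig", "position", "ref", "alt", "strand", "gene_id", "depth", "alt_support"]


def write_events(events: Sequence[EditingEvent], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        [(e.contig, e.position, e.ref, e.alt, e.strand, e.gene_id or ".", e.depth, e.alt_support)
         for e in events],
        columns=EVENT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_events(path: str | os.PathLike) -> list[EditingEvent]:
    frame = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str})
    events = []
    for row in frame.itertuples():
        gene = None if row.gene_id in (".", "nan") or pd.isna(row.gene_id) else row.gene_id
        events.append(EditingEvent(row.contig, int(row.position), gene, row.strand,
                                   row.ref, row.alt, int(row.depth), int(row.alt_support)))
    return events


def substitution_spectrum(calls: Sequence[MismatchCall]) -> pd.Series:
    """Counts of the 12 substitution classes (e.g. for condition comparisons)."""
    idx = [f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a]
    spectrum = pd.Series(0, index=idx, dtype=int)
    for call in calls:
        spectrum[f"{call.ref}>{call.alt}"] += 1
    return spectrum


def call_editing_from_sam(sam_path, reference_path, annotation: UtrAnnotation,
                          snp_db: SiteDb | None = None, editing_db: SiteDb | None = None,
                          min_phred: int = 31, min_alt_reads: int = 2,
                          min_mapq: int = 1, restrict_to_utr: bool = True) -> list[EditingEvent]:
    """Convenience end-to-end path: pileup -> call -> exclude -> events."""
    from .formats import pileup_from_alignments

    pile = pileup_from_alignments(sam_path, reference_path, min_mapq=min_mapq)
    calls = call_mismatches(pile, min_phred=min_phred, min_alt_reads=min_alt_reads)
    calls = exclude_known_sites(calls, snp_db, editing_db)
    return editing_events(calls, annotation, restrict_to_utr=restrict_to_utr)
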