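"""Reading and writing of the standard formats the pipeline touches.

Conventions
-----------
Interval geometry (3'UTR blocks) is stored 0-based half-open, as in BED.
Point positions (pileup columns, variant calls, SNP sites, editing events)
are 1-based, as in SAM and VCF; conversion happens at the BED boundary.

SAM parsing goes through :mod:`pysam`, FASTA access through :mod:`pyfaidx`,
VCF parsing through :class:`pysam.VariantFile`, and GTF line parsing through
:func:`gffutils.feature_from_line`. Gene-level read quantification is a
toy-scale reimplementation of fractional feature counting (a read overlapping
k genes contributes 1/k to each).
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from ._util import logger


class AnnotationParseError(ValueError):
    """Raised with a line number when an annotation or site file is malformed."""


# ---------------------------------------------------------------------------
# 3'UTR annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtrRecord:
    """A transcript 3'UTR: ordered genomic blocks plus strand and biotype.

    ``intervals`` are 0-based half-open (start, end) pairs in genomic order,
    non-overlapping and sorted.
    """

    gene_id: str
    transcript_id: str
    contig: str
    intervals: tuple[tuple[int, int], ...]
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end
        if self.length == 0:
            raise ValueError("record has zero length")

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.intervals)

    def contains(self, contig: str, pos1: int) -> bool:
        """Membership of a 1-based position."""
        if contig != self.contig:
            return False
        pos0 = pos1 - 1
        return any(start <= pos0 < end for start, end in self.intervals)

    def to_local(self, pos1: int) -> int:
        """Project a genomic 1-based position to a 1-based coordinate along the
        concatenated blocks (genomic order). Raises if the position is outside.
        """
        pos0 = pos1 - 1
        offset = 0
        for start, end in self.intervals:
            if start <= pos0 < end:
                return offset + (pos0 - start) + 1
            offset += end - start
        raise ValueError(f"{self.contig}:{pos1} not inside record {self.transcript_id}")


class UtrAnnotation:
    """A set of :class:`UtrRecord` with fast positional lookup."""

    def __init__(self, records: Iterable[UtrRecord]):
        self.records: list[UtrRecord] = list(records)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for rec in self.records:
            for start, end in rec.intervals:
                self._trees[rec.contig].addi(start, end, rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[UtrRecord]:
        return iter(self.records)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.gene_id, None)
        return list(seen)

    def overlapping(self, contig: str, pos1: int) -> list[UtrRecord]:
        """Records whose blocks contain the 1-based position."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree[pos1 - 1]]

    def overlapping_range(self, contig: str, start0: int, end0: int) -> list[UtrRecord]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree[start0:end0]]

    def by_gene(self) -> dict[str, list[UtrRecord]]:
        out: dict[str, list[UtrRecord]] = defaultdict(list)
        for rec in self.records:
            out[rec.gene_id].append(rec)
        return dict(out)


def load_annotation(path: str | os.PathLike, biotype_table: str | os.PathLike | None = None) -> UtrAnnotation:
    """Load a 3'UTR annotation from BED12 (+ biotype TSV) or GTF.

    The BED12 ``name`` field is the transcript id; gene id and biotype come
    from ``biotype_table`` (TSV: transcript_id, gene_id, biotype) when given,
    otherwise gene id defaults to the transcript id with biotype
    ``protein_coding``. GTF input uses ``three_prime_utr`` features, merging
    features of the same transcript into one multi-interval record.
    """
    path = os.fspath(path)
    if path.endswith((".gtf", ".gff")):
        return _load_gtf(path)
    if not path.endswith(".bed"):
        with open(path) as fh:
            first = fh.readline()
            while first.startswith(("#", "track", "browser")):
                first = fh.readline()
        if not first:
            logger.warning("annotation file %s is empty", path)
            return UtrAnnotation([])
        if not _looks_like_bed12(first):
            return _load_gtf(path)
    else:
        with open(path) as fh:
            if not fh.readline():
                logger.warning("annotation file %s is empty", path)
                return UtrAnnotation([])
    meta = _load_biotype_table(biotype_table) if biotype_table else {}
    return _load_bed12(path, meta)


def _looks_like_bed12(line: str) -> bool:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        return False
    try:
        int(fields[1]), int(fields[2]), int(fields[9])
    except ValueError:
        return False
    return True


def _load_biotype_table(path: str | os.PathLike) -> dict[str, tuple[str, str]]:
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["transcript_id", "gene_id", "biotype"], dtype=str)
    if len(table) and table.iloc[0, 0] in ("transcript_id", "transcript"):
        table = table.iloc[1:]
    return {row.transcript_id: (row.gene_id, row.biotype) for row in table.itertuples()}


def _load_bed12(path: str, meta: Mapping[str, tuple[str, str]]) -> UtrAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise AnnotationParseError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationParseError(f"{path}:{lineno}: block count mismatch")
            intervals = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            if intervals and intervals[-1][1] != end:
                raise AnnotationParseError(f"{path}:{lineno}: blocks do not span chromEnd")
            gene_id, biotype = meta.get(name, (name, "protein_coding"))
            records.append(UtrRecord(gene_id=gene_id, transcript_id=name, contig=chrom,
                                     intervals=intervals, strand=strand, biotype=biotype))
    if not records:
        logger.warning("annotation file %s contained no records", path)
    return UtrAnnotation(records)


def _load_gtf(path: str) -> UtrAnnotation:
    from gffutils.feature import feature_from_line

    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line.rstrip("\n"))
            except Exception as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != "three_prime_utr":
                continue
            if feat.strand not in ("+", "-"):
                raise AnnotationParseError(f"{path}:{lineno}: missing strand")
            tx = feat.attributes.get("transcript_id", [None])[0]
            gene = feat.attributes.get("gene_id", [tx])[0]
            biotype = (feat.attributes.get("transcript_biotype", None)
                       or feat.attributes.get("gene_biotype", ["protein_coding"]))[0]
            if tx is None:
                raise AnnotationParseError(f"{path}:{lineno}: no transcript_id attribute")
            entry = per_tx.setdefault(tx, {"gene": gene, "contig": feat.seqid,
                                           "strand": feat.strand, "biotype": biotype,
                                           "intervals": []})
            entry["intervals"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive
    records = []
    for tx, entry in per_tx.items():
        intervals = tuple(sorted(entry["intervals"]))
        records.append(UtrRecord(gene_id=entry["gene"], transcript_id=tx, contig=entry["contig"],
                                 intervals=intervals, strand=entry["strand"], biotype=entry["biotype"]))
    if not records:
        logger.warning("annotation file %s contained no three_prime_utr features", path)
    return UtrAnnotation(records)


def write_annotation(annotation: UtrAnnotation, bed_path: str | os.PathLike,
                     biotype_path: str | os.PathLike | None = None) -> None:
    """Write BED12 (+ optional transcript/gene/biotype TSV)."""
    with open(bed_path, "w") as fh:
        for rec in annotation:
            start = rec.intervals[0][0]
            end = rec.intervals[-1][1]
            sizes = ",".join(str(e - s) for s, e in rec.intervals)
            starts = ",".join(str(s - start) for s, _ in rec.intervals)
            fh.write("\t".join(map(str, [rec.contig, start, end, rec.transcript_id, 0,
                                         rec.strand, start, end, "0,0,0",
                                         len(rec.intervals), sizes, starts])) + "\n")
    if biotype_path is not None:
        with open(biotype_path, "w") as fh:
            for rec in annotation:
                fh.write(f"{rec.transcript_id}\t{rec.gene_id}\t{rec.biotype}\n")


# ---------------------------------------------------------------------------
# SNP / known-editing site databases
# ---------------------------------------------------------------------------

class SiteDb:
    """Deduplicated set of (contig, 1-based position) keys with a source tag."""

    def __init__(self, sites: Iterable[tuple[str, int]] = (), source: str = "SNP"):
        self.source = source
        self._sites: frozenset[tuple[str, int]] = frozenset((str(c), int(p)) for c, p in sites)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return (str(key[0]), int(key[1])) in self._sites

    def __len__(self) -> int:
        return len(self._sites)

    def __or__(self, other: "SiteDb") -> "SiteDb":
        merged = SiteDb(source=f"{self.source}+{other.source}")
        merged._sites = self._sites | other._sites
        return merged


def load_site_db(path: str | os.PathLike, source: str = "SNP") -> SiteDb:
    """Load known sites from a VCF (via pysam) or a 2-column contig/position TSV.

    A TSV header line is tolerated and skipped; positions are 1-based.
    """
    path = os.fspath(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        sites = []
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                sites.append((rec.chrom, rec.pos))
        return SiteDb(sites, source=source)
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                if lineno == 1:  # header row
                    continue
                raise AnnotationParseError(f"{path}:{lineno}: non-integer position {fields[1]!r}") from exc
            sites.append((fields[0], pos))
    return SiteDb(sites, source=source)


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class PileupColumn:
    """All read observations at one reference position (1-based)."""

    contig: str
    position: int
    ref_base: str
    bases: list[str] = field(default_factory=list)
    quals: list[int] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.bases)


def pileup_from_alignments(sam_path: str | os.PathLike,
                           reference_path: str | os.PathLike,
                           region: str | None = None,
                           min_mapq: int = 1,
                           include_duplicates: bool = False) -> Iterator[PileupColumn]:
    """Linear-scan pileup over a SAM file.

    Skips unmapped, secondary, supplementary and (by default) duplicate-flagged
    reads, and reads below ``min_mapq``. Insertions are ignored; deleted
    reference positions receive no observation. ``region``, when given, is a
    contig name restricting the scan.
    """
    import pyfaidx

    fasta = pyfaidx.Fasta(os.fspath(reference_path))
    columns: dict[str, dict[int, PileupColumn]] = defaultdict(dict)
    contig_order: list[str] = []
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate and not include_duplicates:
                continue
            if read.mapping_quality < min_mapq:
                continue
            contig = read.reference_name
            if region is not None and contig != region:
                continue
            if contig not in columns:
                contig_order.append(contig)
            seq = read.query_sequence
            quals = read.query_qualities
            strand = "-" if read.is_reverse else "+"
            cols = columns[contig]
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                col = cols.get(rpos)
                if col is None:
                    ref_base = str(fasta[contig][rpos]).upper()
                    col = cols[rpos] = PileupColumn(contig, rpos + 1, ref_base)
                col.bases.append(seq[qpos])
                col.quals.append(quals[qpos] if quals is not None else 0)
                col.strands.append(strand)
    for contig in contig_order:
        for rpos in sorted(columns[contig]):
            yield columns[contig][rpos]


# ---------------------------------------------------------------------------
# Gene-level quantification
# ---------------------------------------------------------------------------

def quantify_genes(sam_path: str | os.PathLike, annotation: UtrAnnotation,
                   fractional: bool = True, min_mapq: int = 1) -> pd.Series:
    """Gene-level read counting with fractional multi-overlap assignment.

    A read overlapping k annotated genes contributes 1/k to each when
    ``fractional`` is on; with it off, multi-overlap reads are dropped.
    Read strand is ignored (gene strand comes solely from the annotation).
    """
    counts: dict[str, float] = {g: 0.0 for g in annotation.genes()}
    with pysam.AlignmentFile(os.fspath(sam_path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            hits = annotation.overlapping_range(read.reference_name,
                                                read.reference_start, read.reference_end)
            genes = sorted({rec.gene_id for rec in hits})
            if not genes:
                continue
            if len(genes) > 1 and not fractional:
                continue
            share = 1.0 / len(genes)
            for g in genes:
                counts[g] += share
    return pd.Series(counts, name="count")
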