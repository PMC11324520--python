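"""Fully self-contained synthetic experiments with ground-truth manifests.

The generator emulates the statistical structure the analysis assumes:

* a toy genome of one contig per gene, each with one transcript whose single
  3'UTR carries planted editing sites on transcript-strand adenosines;
* paired bulk alignment sets for a fusion-protein condition (elevated
  per-read editing at planted sites of target genes), a deaminase-only
  condition (background editing everywhere) and an untransfected control
  (no editing), with heterozygous SNP alleles and uniform sequencing errors
  as confounders and two-valued base qualities so the Phred filter has a
  crisp boundary;
* negative-binomial expression count tables where target genes are
  derepressed by a configured log2 fold change in the miRNA-inhibited
  scenario, with library sizes varied up to three-fold;
* single cells spanning cell-cycle phases with linker reads in transfected
  cells, per-cell spike-in reads and optional phase-specific editing.

Alignments are emitted ungapped (pure matches with substitutions). All
randomness flows from the config seed through named substreams, so identical
configs give byte-identical outputs. Single-cell read counts are scaled down
roughly 100x from full-scale plate-based depth; QC thresholds in tests scale
accordingly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._util import child_seed, logger, revcomp
from .formats import UtrAnnotation, UtrRecord

CONDITIONS = ("agoTRIBE", "ADAR-only", "control")
EXCLUDED_BIOTYPE_CYCLE = ("nonsense_mediated_decay", "retained_intron",
                          "processed_transcript", "non_stop_decay",
                          "unprocessed_pseudogene")
PHASES = ("G1", "S", "G2M")


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic experiment.

    Editing rates are per-read probabilities at planted sites; the true
    per-adenosine rate induced in cells is unknown, so the defaults are
    chosen once for statistical power at toy depth.
    """

    n_genes: int = 1000
    utr_length_range: tuple[int, int] = (200, 400)
    editing_rate_target: float = 0.5       # planted sites of target genes, fusion condition
    editing_rate_background: float = 0.05  # planted sites elsewhere / deaminase-only condition
    edited_site_fraction: float = 0.2      # fraction of UTR adenosines carrying a planted site
    snp_density: float = 0.002             # per-bp probability of a heterozygous SNP
    seq_error_rate: float = 0.001          # per-base uniform error probability
    low_quality_fraction: float = 0.1      # fraction of bases below the Phred-31 cutoff
    base_qualities: tuple[int, int] = (20, 37)
    read_length: int = 75
    depth_mean: float = 30.0               # reads per gene (Poisson mean)
    n_target_genes: int = 50
    excluded_biotype_fraction: float = 0.1
    flank: int = 50
    # expression counts
    expression_mean: float = 400.0
    expression_sigma: float = 0.8
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    derepression_log2fc: float = 0.18
    # single cells
    n_cells: int = 100
    transfected_fraction: float = 0.8
    linker_expression_mean: float = 50.0
    linker_false_hit_rate: float = 0.0
    linker_length: int = 165               # 55 codons
    spikein_total: float = 500.0
    n_spikein_contigs: int = 10
    sc_expression_mean: float = 20.0
    sc_editing_per_target: float = 3.0
    sc_editing_background: float = 0.05
    n_marker_genes: int = 30
    marker_fold: float = 4.0
    phase_edited_genes: tuple[tuple[str, str], ...] = ()   # (gene, phase) pairs
    seed: int = 0

    def validate(self) -> None:
        probs = dict(editing_rate_target=self.editing_rate_target,
                     editing_rate_background=self.editing_rate_background,
                     edited_site_fraction=self.edited_site_fraction,
                     snp_density=self.snp_density, seq_error_rate=self.seq_error_rate,
                     low_quality_fraction=self.low_quality_fraction,
                     transfected_fraction=self.transfected_fraction,
                     excluded_biotype_fraction=self.excluded_biotype_fraction,
                     linker_false_hit_rate=self.linker_false_hit_rate)
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        if self.editing_rate_target <= self.editing_rate_background:
            raise InvalidConfigError("editing_rate_target must exceed editing_rate_background")
        lo, hi = self.utr_length_range
        if lo > hi or lo < 10:
            raise InvalidConfigError(
                "utr_length_range too small to guarantee 10 adenosines per 3'UTR")
        if lo < self.read_length:
            raise InvalidConfigError(
                f"minimum UTR length {lo} shorter than read_length {self.read_length}")
        if self.n_target_genes > self.n_genes:
            raise InvalidConfigError("n_target_genes cannot exceed n_genes")


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    contig: str
    position: int   # 1-based
    strand: str     # transcript strand
    rate: float     # per-read editing rate in the fusion condition


@dataclass
class TruthManifest:
    edited_sites: list[PlantedSite]
    snp_sites: list[tuple[str, int, str, str]]   # contig, 1-based pos, ref, alt
    target_genes: set[str]
    linker_seq: str = ""
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    cells: pd.DataFrame | None = None            # per-cell truth

    def sites_by_contig(self) -> dict[str, list[PlantedSite]]:
        out: dict[str, list[PlantedSite]] = {}
        for site in self.edited_sites:
            out.setdefault(site.contig, []).append(site)
        return out

    def snps_by_contig(self) -> dict[str, list[tuple[int, str, str]]]:
        out: dict[str, list[tuple[int, str, str]]] = {}
        for contig, pos, ref, alt in self.snp_sites:
            out.setdefault(contig, []).append((pos, ref, alt))
        return out


# ---------------------------------------------------------------------------
# Reference + annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def gen_reference_and_annotation(config: SimulationConfig) \
        -> tuple[dict[str, str], UtrAnnotation, TruthManifest]:
    """Toy genome (one contig per gene), 3'UTR annotation and truth manifest.

    Every 3'UTR is guaranteed >= 10 transcript-strand adenosines (reference A
    on plus-strand genes, reference T on minus-strand genes); a configured
    fraction of genes receives an excluded decay/pseudogene biotype, and
    target genes are drawn from the protein-coding remainder.
    """
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "reference"))
    lo, hi = config.utr_length_range
    n = config.n_genes
    width = max(4, len(str(n)))
    reference: dict[str, str] = {}
    records: list[UtrRecord] = []
    sites: list[PlantedSite] = []
    snps: list[tuple[str, int, str, str]] = []

    n_excluded = round(config.excluded_biotype_fraction * n)
    excluded_idx = set(rng.choice(n, size=n_excluded, replace=False).tolist())
    coding = [i for i in range(n) if i not in excluded_idx]
    if config.n_target_genes > len(coding):
        raise InvalidConfigError("not enough protein-coding genes for the requested targets")
    target_idx = set(rng.choice(len(coding), size=config.n_target_genes, replace=False).tolist())
    targets = {f"g{coding[i]:0{width}d}" for i in target_idx}

    excl_cycle = 0
    for i in range(n):
        gene = f"g{i:0{width}d}"
        contig = gene
        strand = "+" if rng.random() < 0.5 else "-"
        utr_len = int(rng.integers(lo, hi + 1))
        contig_len = 2 * config.flank + utr_len
        seq = _random_seq(rng, contig_len)
        utr_start, utr_end = config.flank, config.flank + utr_len

        sense_base = ord("A") if strand == "+" else ord("T")
        utr = seq[utr_start:utr_end]
        a_pos = np.flatnonzero(utr == sense_base)
        if a_pos.size < 10:   # force enough transcript-strand adenosines
            deficit = 10 - a_pos.size
            candidates = np.setdiff1d(np.arange(utr_len), a_pos)
            extra = rng.choice(candidates, size=deficit, replace=False)
            utr[extra] = sense_base
            a_pos = np.flatnonzero(utr == sense_base)
        seq[utr_start:utr_end] = utr

        planted_mask = rng.random(a_pos.size) < config.edited_site_fraction
        planted = a_pos[planted_mask]
        rate = config.editing_rate_target if gene in targets else config.editing_rate_background
        site_positions = set()
        for p in planted:
            pos1 = utr_start + int(p) + 1
            sites.append(PlantedSite(gene, contig, pos1, strand, rate))
            site_positions.add(pos1)

        snp_mask = rng.random(contig_len) < config.snp_density
        for p in np.flatnonzero(snp_mask):
            pos1 = int(p) + 1
            if pos1 in site_positions:
                continue   # keep SNP and editing truth disjoint
            ref = chr(seq[p])
            alt = chr(int(rng.choice(_BASES[_BASES != seq[p]])))
            snps.append((contig, pos1, ref, alt))

        if i in excluded_idx:
            biotype = EXCLUDED_BIOTYPE_CYCLE[excl_cycle % len(EXCLUDED_BIOTYPE_CYCLE)]
            excl_cycle += 1
        else:
            biotype = "protein_coding"
        reference[contig] = seq.tobytes().decode()
        records.append(UtrRecord(gene_id=gene, transcript_id=f"t{i:0{width}d}", contig=contig,
                                 intervals=((utr_start, utr_end),), strand=strand,
                                 biotype=biotype))

    linker_rng = np.random.default_rng(child_seed(config.seed, "linker"))
    linker_seq = _random_seq(linker_rng, config.linker_length).tobytes().decode()
    truth = TruthManifest(edited_sites=sites, snp_sites=snps, target_genes=targets,
                          linker_seq=linker_seq)
    return reference, UtrAnnotation(records), truth


def gen_spikein_reference(config: SimulationConfig) -> dict[str, str]:
    """ERCC-style spike-in contigs (named ``ERCC-0001`` ...)."""
    rng = np.random.default_rng(child_seed(config.seed, "spikein-ref"))
    return {f"ERCC-{i + 1:04d}": _random_seq(rng, 200).tobytes().decode()
            for i in range(config.n_spikein_contigs)}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_snp_vcf(truth: TruthManifest, reference: dict[str, str],
                  path: str | os.PathLike) -> None:
    """Minimal VCF of the planted heterozygous SNP sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, seq in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt in sorted(truth.snp_sites):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def write_truth_sites(truth: TruthManifest, path: str | os.PathLike) -> None:
    frame = pd.DataFrame([(s.gene_id, s.contig, s.position, s.strand, s.rate)
                          for s in truth.edited_sites],
                         columns=["gene_id", "contig", "position", "strand", "rate"])
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    contig: str
    start0: int
    seq: str
    quals: np.ndarray
    reverse: bool
    name: str


class AlignmentSet:
    """In-memory ungapped alignments with a SAM writer (coordinate-sorted)."""

    def __init__(self, contigs: dict[str, int], reads: list[SimRead]):
        self.contigs = contigs
        self.reads = reads

    def __len__(self) -> int:
        return len(self.reads)

    def write_sam(self, path: str | os.PathLike) -> None:
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": name, "LN": length} for name, length in self.contigs.items()]}
        tids = {name: i for i, name in enumerate(self.contigs)}
        ordered = sorted(self.reads, key=lambda r: (tids[r.contig], r.start0, r.name))
        with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
            for read in ordered:
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = read.name
                seg.flag = 16 if read.reverse else 0
                seg.reference_id = tids[read.contig]
                seg.reference_start = read.start0
                seg.mapping_quality = 60
                seg.cigartuples = [(0, len(read.seq))]
                seg.query_sequence = read.seq
                seg.query_qualities = read.quals.tolist()
                out.write(seg)


def _condition_rate(site: PlantedSite, condition: str, config: SimulationConfig) -> float:
    if condition == "agoTRIBE":
        return site.rate
    if condition == "ADAR-only":
        return config.editing_rate_background
    return 0.0   # control: no deaminase activity


def _simulate_gene_reads(rng: np.random.Generator, config: SimulationConfig,
                         seq: str, rec: UtrRecord, sites: Sequence[PlantedSite],
                         snps: Sequence[tuple[int, str, str]], condition: str,
                         n_reads: int, name_prefix: str) -> list[SimRead]:
    lo_q, hi_q = config.base_qualities
    utr_start, utr_end = rec.intervals[0]
    read_len = config.read_length
    max_start = utr_end - read_len
    contig_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    reads: list[SimRead] = []
    edited_base = ord("G") if rec.strand == "+" else ord("C")
    for k in range(n_reads):
        start = int(rng.integers(utr_start, max_start + 1))
        bases = contig_arr[start:start + read_len].copy()
        for site in sites:
            off = site.position - 1 - start
            if 0 <= off < read_len:
                rate = _condition_rate(site, condition, config)
                if rate > 0 and rng.random() < rate:
                    bases[off] = edited_base
        for pos1, _ref, alt in snps:
            off = pos1 - 1 - start
            if 0 <= off < read_len and rng.random() < 0.5:   # heterozygous allele
                bases[off] = ord(alt)
        err_mask = rng.random(read_len) < config.seq_error_rate
        for off in np.flatnonzero(err_mask):
            bases[off] = int(rng.choice(_BASES[_BASES != bases[off]]))
        quals = np.where(rng.random(read_len) < config.low_quality_fraction, lo_q, hi_q)
        reads.append(SimRead(rec.contig, start, bases.tobytes().decode(),
                             quals.astype(np.uint8), bool(rng.random() < 0.5),
                             f"{name_prefix}:{rec.contig}:{k}"))
    return reads


def gen_bulk_alignments(config: SimulationConfig, reference: dict[str, str],
                        annotation: UtrAnnotation, truth: TruthManifest,
                        condition: str) -> AlignmentSet:
    """Ungapped bulk reads over every gene's 3'UTR for one condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "bulk", condition))
    sites_by_contig = truth.sites_by_contig()
    snps_by_contig = truth.snps_by_contig()
    reads: list[SimRead] = []
    for rec in annotation:
        n_reads = int(rng.poisson(config.depth_mean))
        reads.extend(_simulate_gene_reads(
            rng, config, reference[rec.contig], rec,
            sites_by_contig.get(rec.contig, ()), snps_by_contig.get(rec.contig, ()),
            condition, n_reads, condition.replace("-", "")))
    contigs = {name: len(seq) for name, seq in reference.items()}
    return AlignmentSet(contigs, reads)


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _base_expression_means(config: SimulationConfig, genes: Sequence[str]) -> pd.Series:
    """Per-gene baseline means, shared between scenarios (seeded independently
    of the scenario so fold changes are well defined)."""
    rng = np.random.default_rng(child_seed(config.seed, "expression-means"))
    means = rng.lognormal(mean=math.log(config.expression_mean),
                          sigma=config.expression_sigma, size=len(genes))
    return pd.Series(means, index=list(genes))


def gen_expression_counts(config: SimulationConfig, annotation: UtrAnnotation,
                          truth: TruthManifest, scenario: str) -> pd.DataFrame:
    """Negative-binomial gene x sample counts for one scenario.

    In the ``T6B`` (miRNA-inhibited) scenario truth target genes have their
    mean multiplied by 2**derepression_log2fc; library sizes vary up to
    three-fold to exercise between-sample normalization.
    """
    if scenario not in ("T6B", "control"):
        raise ValueError("scenario must be 'T6B' or 'control'")
    config.validate()
    genes = annotation.genes()
    means = _base_expression_means(config, genes)
    if scenario == "T6B" and config.derepression_log2fc != 0:
        bump = 2.0 ** config.derepression_log2fc
        means = means * pd.Series({g: bump if g in truth.target_genes else 1.0 for g in genes})
    rng = np.random.default_rng(child_seed(config.seed, "expression", scenario))
    lib_factors = rng.uniform(1.0, 3.0, size=config.n_replicates)
    disp = config.nb_dispersion
    size = 1.0 / disp
    cols = {}
    for r in range(config.n_replicates):
        mu = means.to_numpy() * lib_factors[r]
        p = size / (size + mu)
        cols[f"{scenario}_{r + 1}"] = rng.negative_binomial(size, p)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# Single cells
# ---------------------------------------------------------------------------

@dataclass
class SingleCellData:
    """Bundle of synthetic single-cell outputs.

    ``metadata`` has one row per cell (truth columns included);
    ``expression`` and ``editing`` are genes x cells count matrices;
    ``linker_reads`` are the raw unaligned linker-derived sequences per cell
    (the alignment-based path sees the same reads on the ``linker`` contig of
    each cell's SAM).
    """

    metadata: pd.DataFrame
    expression: pd.DataFrame
    editing: pd.DataFrame
    linker_reads: dict[str, list[str]]
    config: SimulationConfig
    truth: TruthManifest

    def write_cell_sam(self, cell_id: str, path: str | os.PathLike,
                       reference: dict[str, str], annotation: UtrAnnotation,
                       n_genes_in_sam: int = 3) -> None:
        """A small per-cell SAM: a few gene reads, linker-contig reads and
        spike-in reads (deterministic per cell)."""
        cfg = self.config
        rng = np.random.default_rng(child_seed(cfg.seed, "sc-sam", cell_id))
        row = self.metadata.loc[self.metadata["cell_id"] == cell_id].iloc[0]
        spike_ref = gen_spikein_reference(cfg)
        contigs = {name: len(seq) for name, seq in reference.items()}
        contigs["linker"] = len(self.truth.linker_seq)
        contigs.update({name: len(seq) for name, seq in spike_ref.items()})
        reads: list[SimRead] = []
        condition = "agoTRIBE" if row["transfected"] else "control"
        sites_by_contig = self.truth.sites_by_contig()
        snps_by_contig = self.truth.snps_by_contig()
        for rec in list(annotation)[:n_genes_in_sam]:
            reads.extend(_simulate_gene_reads(
                rng, cfg, reference[rec.contig], rec,
                sites_by_contig.get(rec.contig, ()), snps_by_contig.get(rec.contig, ()),
                condition, int(rng.poisson(5)), f"{cell_id}"))
        hi_q = cfg.base_qualities[1]
        for i, seq in enumerate(self.linker_reads.get(cell_id, [])):
            reads.append(SimRead("linker", 0, seq,
                                 np.full(len(seq), hi_q, dtype=np.uint8), False,
                                 f"{cell_id}:linker:{i}"))
        spike_names = list(spike_ref)
        n_spike = int(row["spike_reads"])
        for i in range(n_spike):
            contig = spike_names[int(rng.integers(0, len(spike_names)))]
            seq = spike_ref[contig]
            start = int(rng.integers(0, max(1, len(seq) - cfg.read_length + 1)))
            sub = seq[start:start + cfg.read_length]
            reads.append(SimRead(contig, start, sub,
                                 np.full(len(sub), hi_q, dtype=np.uint8), False,
                                 f"{cell_id}:spike:{i}"))
        AlignmentSet(contigs, reads).write_sam(path)


def _exact_allocation(rng: np.random.Generator, n: int, labels: Sequence[str]) -> np.ndarray:
    """Deterministically balanced assignment of n items to labels (shuffled)."""
    reps = np.array([n // len(labels)] * len(labels))
    reps[: n - reps.sum()] += 1
    out = np.repeat(np.array(labels, dtype=object), reps)
    rng.shuffle(out)
    return out


def gen_single_cells(config: SimulationConfig, reference: dict[str, str],
                     annotation: UtrAnnotation, truth: TruthManifest) -> SingleCellData:
    """Synthetic single cells: metadata, expression, editing and linker reads.

    Cells are assigned to G1/S/G2M in equal proportions (exact allocation) and
    split into transfected / untransfected at exactly the configured fraction.
    Transfected cells receive Poisson linker reads and elevated editing of
    target genes; untransfected cells receive (by default) zero linker reads
    and background editing. Phase-specific editing of designated genes is
    honoured via ``config.phase_edited_genes``. Every cell receives spike-in
    reads.
    """
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "single-cells"))
    n = config.n_cells
    genes = annotation.genes()
    cell_ids = [f"cell{i:04d}" for i in range(n)]
    phases = _exact_allocation(rng, n, PHASES)
    n_transfected = round(config.transfected_fraction * n)
    transfected = np.zeros(n, dtype=bool)
    transfected[rng.choice(n, size=n_transfected, replace=False)] = True

    # marker genes for S and G2M scores, drawn from non-target coding genes
    coding = [g for g in genes if g not in truth.target_genes]
    marker_rng = np.random.default_rng(child_seed(config.seed, "markers"))
    n_marker = min(config.n_marker_genes, len(coding) // 2)  # small toy genomes
    picked = marker_rng.choice(len(coding), size=2 * n_marker, replace=False)
    s_markers = [coding[i] for i in picked[:n_marker]]
    g2m_markers = [coding[i] for i in picked[n_marker:]]
    truth.marker_genes = {"S": s_markers, "G2M": g2m_markers}

    means = _base_expression_means(config, genes)
    means = means / means.mean() * config.sc_expression_mean
    mean_arr = means.to_numpy()
    gene_index = {g: i for i, g in enumerate(genes)}
    s_idx = np.array([gene_index[g] for g in s_markers])
    g2m_idx = np.array([gene_index[g] for g in g2m_markers])
    target_idx = np.array([gene_index[g] for g in truth.target_genes if g in gene_index])
    phase_edit = {(gene_index[g], ph) for g, ph in config.phase_edited_genes if g in gene_index}

    size = 1.0 / config.nb_dispersion
    expr = np.empty((len(genes), n), dtype=np.int64)
    edit = np.zeros((len(genes), n), dtype=np.int64)
    cell_scale = rng.lognormal(0.0, 0.2, size=n)
    for j in range(n):
        mu = mean_arr * cell_scale[j]
        if phases[j] == "S":
            mu = mu.copy(); mu[s_idx] *= config.marker_fold
        elif phases[j] == "G2M":
            mu = mu.copy(); mu[g2m_idx] *= config.marker_fold
        p = size / (size + mu)
        expr[:, j] = rng.negative_binomial(size, p)
        lam = np.full(len(genes), config.sc_editing_background)
        if transfected[j]:
            lam[target_idx] = config.sc_editing_per_target
            for gi, ph in phase_edit:
                lam[gi] = config.sc_editing_per_target if phases[j] == ph \
                    else config.sc_editing_background
        edit[:, j] = rng.poisson(lam)

    linker_reads: dict[str, list[str]] = {}
    linker = truth.linker_seq
    linker_arr = np.frombuffer(linker.encode(), dtype=np.uint8)
    read_len = min(config.read_length, len(linker))
    for j, cid in enumerate(cell_ids):
        if transfected[j]:
            k = int(rng.poisson(config.linker_expression_mean))
        else:
            k = int(rng.poisson(config.linker_false_hit_rate))
        seqs = []
        for _ in range(k):
            start = int(rng.integers(0, len(linker) - read_len + 1))
            sub = linker_arr[start:start + read_len].copy()
            err = rng.random(read_len) < config.seq_error_rate
            for off in np.flatnonzero(err):
                sub[off] = int(rng.choice(_BASES[_BASES != sub[off]]))
            seq = sub.tobytes().decode()
            if rng.random() < 0.5:
                seq = revcomp(seq)
            seqs.append(seq)
        linker_reads[cid] = seqs

    spike_reads = rng.poisson(config.spikein_total, size=n)
    expr_frame = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=cell_ids)
    edit_frame = pd.DataFrame(edit, index=pd.Index(genes, name="gene_id"), columns=cell_ids)
    gene_counts = (expr_frame > 0).sum(axis=0).to_numpy()
    linker_raw = np.array([len(linker_reads[c]) for c in cell_ids])
    editing_total = edit_frame.sum(axis=0).to_numpy()
    total_reads = expr_frame.sum(axis=0).to_numpy() + linker_raw + spike_reads
    metadata = pd.DataFrame({
        "cell_id": cell_ids,
        "phase_truth": phases,
        "transfected": transfected,
        "detected_genes": gene_counts,
        "total_reads": total_reads,
        "dedup_reads": (0.8 * total_reads).round().astype(int),
        "linker_raw": linker_raw,
        "editing_events": editing_total,
        "spike_reads": spike_reads,
    })
    truth.cells = metadata[["cell_id", "phase_truth", "transfected", "editing_events"]].copy()
    return SingleCellData(metadata=metadata, expression=expr_frame, editing=edit_frame,
                          linker_reads=linker_reads, config=config, truth=truth)
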