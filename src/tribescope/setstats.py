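"""Target-set comparison statistics: Jaccard similarity, binomial overlap
enrichment, fold ratios and ranked-list union compilation.

The binomial convention: drawing ``|a|`` genes from a universe in which a
fraction ``|b|/universe`` belongs to the other set, the upper-tail
probability of observing at least the actual intersection size. The
convention is recorded in the result so outputs are self-describing.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene: str, case_fold: bool = True, strip_version: bool = True) -> str:
    gene = gene.strip()
    if strip_version:
        gene = _VERSION_SUFFIX.sub("", gene)
    return gene.upper() if case_fold else gene


@dataclass(frozen=True)
class TargetSet:
    """A labelled gene set, optionally with the size of its gene universe."""

    label: str
    genes: frozenset[str]
    universe: int | None = None

    def __post_init__(self) -> None:
        if self.universe is not None and self.universe < len(self.genes):
            raise ValueError("universe smaller than the set itself")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_genes(cls, label: str, genes: Iterable[str], universe: int | None = None,
                   case_fold: bool = True, strip_version: bool = True) -> "TargetSet":
        return cls(label, frozenset(normalize_gene_id(g, case_fold, strip_version)
                                    for g in genes), universe)

    @classmethod
    def from_file(cls, path: str | os.PathLike, label: str | None = None,
                  universe: int | None = None) -> "TargetSet":
        """One gene id per line; an optional second TSV column (rank/score) is ignored."""
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    genes.append(line.split("\t")[0])
        return cls.from_genes(label or os.path.basename(os.fspath(path)), genes, universe)


def jaccard(a: TargetSet, b: TargetSet) -> float:
    """|a ∩ b| / |a ∪ b|; 0.0 when both sets are empty."""
    union = a.genes | b.genes
    if not union:
        return 0.0
    return len(a.genes & b.genes) / len(union)


@dataclass(frozen=True)
class OverlapResult:
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    convention: str = field(default="upper tail of Binomial(n=|a|, p=|b|/universe) at k=|a∩b|")


def overlap_binomial(a: TargetSet, b: TargetSet, universe: int | None = None) -> OverlapResult:
    """Enrichment of the overlap between two sets against a binomial null."""
    if universe is None:
        universe = a.universe or b.universe
    if universe is None:
        raise ValueError("a universe size is required")
    if universe < len(a.genes | b.genes):
        raise ValueError(f"universe {universe} smaller than |a ∪ b| = {len(a.genes | b.genes)}")
    k = len(a.genes & b.genes)
    p = len(b) / universe
    expected = len(a) * p
    # upper tail P(X >= k); sf(k-1) so that k=0 gives exactly 1
    p_value = float(stats.binom.sf(k - 1, len(a), p)) if k > 0 else 1.0
    fold = k / expected if expected > 0 else float("nan")
    return OverlapResult(observed=k, expected=expected, fold_enrichment=fold, p_value=p_value)


def fold_ratio(k1: int, k2: int) -> float:
    """Ratio of two overlap counts (e.g. guided vs deaminase-only overlap)."""
    if k2 <= 0:
        raise ValueError("denominator count must be positive")
    return k1 / k2


def compile_target_union(lists: Sequence[Sequence[str]] | Sequence[TargetSet],
                         top_n_per_list: int | None = None,
                         labels: Sequence[str] | None = None) -> tuple[TargetSet, pd.DataFrame]:
    """Union of the top-N entries of several ranked gene lists.

    Returns the deduplicated union set and a provenance table recording, for
    every gene, which source lists contributed it.
    """
    prepared: list[tuple[str, list[str]]] = []
    for i, item in enumerate(lists):
        if isinstance(item, TargetSet):
            prepared.append((item.label, sorted(item.genes)))
        else:
            label = labels[i] if labels else f"list{i + 1}"
            prepared.append((label, [normalize_gene_id(g) for g in item]))
    membership: dict[str, dict[str, bool]] = {}
    for label, genes in prepared:
        take = genes if top_n_per_list is None else genes[:top_n_per_list]
        for g in take:
            membership.setdefault(g, {})[label] = True
    table = pd.DataFrame.from_dict(membership, orient="index").astype("boolean").fillna(False).astype(bool)
    table = table.reindex(columns=[label for label, _ in prepared], fill_value=False)
    table.index.name = "gene_id"
    union = TargetSet("union", frozenset(membership))
    return union, table


def membership_counts(table: pd.DataFrame) -> pd.Series:
    """Venn-style counts: how many genes fall in each combination of sources."""
    key = table.apply(lambda row: "&".join(col for col in table.columns if row[col]) or "none", axis=1)
    return key.value_counts().sort_index()
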