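"""Per-3'UTR editing aggregation and regression-residual target ranking.

Genes are ranked by how much more editing they accumulate in the
fusion-protein (test) condition than expected from their editing in the
deaminase-only (background) condition. The expectation is an ordinary
least-squares fit of test-condition events on background-condition events
across genes; internally studentized residuals are the ranking statistic.
The top-K residuals define the guided target set, the bottom-K the
background (deaminase-intrinsic) set.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from ._util import logger
from .editcall import EditingEvent
from .formats import UtrAnnotation

#: transcript biotypes removed before aggregation (decay/retained/pseudogene classes)
DEFAULT_EXCLUDED_BIOTYPES = frozenset({
    "nonsense_mediated_decay",
    "non_stop_decay",
    "processed_transcript",
    "retained_intron",
    "unprocessed_pseudogene",
})


def aggregate_utr_editing(events_by_sample: Mapping[str, Sequence[EditingEvent]],
                          annotation: UtrAnnotation,
                          excluded_biotypes: Iterable[str] = DEFAULT_EXCLUDED_BIOTYPES,
                          conditions: Mapping[str, str] | None = None,
                          collapse: bool = True) -> pd.DataFrame:
    """Gene x sample matrix of editing-event counts over annotated 3'UTRs.

    Genes whose transcripts all carry excluded biotypes are absent from the
    matrix; genes with no events appear with zero counts. Events referencing
    unknown or excluded genes are skipped with a warning. When ``conditions``
    maps sample names to condition labels and ``collapse`` is on, replicate
    columns of a condition are summed into one column.
    """
    excluded = set(excluded_biotypes)
    retained: list[str] = []
    by_gene = annotation.by_gene()
    for gene, recs in by_gene.items():
        if any(rec.biotype not in excluded for rec in recs):
            retained.append(gene)
    samples = list(events_by_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("sample labels must be unique")
    matrix = pd.DataFrame(0, index=pd.Index(retained, name="gene_id"), columns=samples, dtype=int)
    retained_set = set(retained)
    for sample, events in events_by_sample.items():
        skipped = 0
        for ev in events:
            if ev.gene_id in retained_set:
                matrix.at[ev.gene_id, sample] += 1
            else:
                skipped += 1
        if skipped:
            logger.warning("sample %s: skipped %d events on unknown/excluded genes", sample, skipped)
    if conditions and collapse:
        matrix = matrix.T.groupby(pd.Series(conditions)).sum().T
    return matrix


def rank_residuals(matrix: pd.DataFrame, test_condition: str, background_condition: str,
                   studentized: bool = True, log1p: bool = False) -> pd.DataFrame:
    """OLS of test-condition events on background-condition events, genes ranked
    by (internally studentized) residual, descending.

    Returns a DataFrame indexed by gene with columns ``x`` (background events),
    ``y`` (test events), ``fitted``, ``std_residual``, ``rank`` and ``class``
    (filled by :func:`select_top_background`; initialised to ``neither``).
    Ties break by gene id ascending. A background column with zero variance is
    rejected with a pointer to ranking by ``y`` directly.
    """
    x = matrix[background_condition].astype(float)
    y = matrix[test_condition].astype(float)
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    if len(matrix) < 3:
        raise ValueError("need at least 3 genes to fit the regression")
    if float(np.var(x)) == 0.0:
        raise ValueError(
            "background condition has zero variance across genes; the regression is "
            "undefined — rank genes by the test-condition counts (y) instead")
    design = sm.add_constant(x.to_numpy())
    fit = sm.OLS(y.to_numpy(), design).fit()
    if studentized:
        if fit.mse_resid < 1e-12:
            resid = np.zeros(len(y))
        else:
            resid = OLSInfluence(fit).resid_studentized_internal
    else:
        resid = fit.resid
    out = pd.DataFrame({
        "x": x.to_numpy(), "y": y.to_numpy(), "fitted": fit.fittedvalues,
        "std_residual": resid,
    }, index=matrix.index)
    # mergesort is stable; pre-sort index ascending so residual ties break by gene id
    out = out.loc[sorted(out.index)].sort_values("std_residual", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out["class"] = "neither"
    return out


def select_top_background(ranked: pd.DataFrame, k_top: int = 1000,
                          k_bg: int = 1000) -> tuple[set[str], set[str]]:
    """Top-``k_top`` residuals as guided targets, bottom-``k_bg`` as background.

    When the gene universe is too small, both K shrink to half the universe
    (with a warning) so the sets stay disjoint. The input frame's ``class``
    column is annotated in place.
    """
    n = len(ranked)
    if k_top + k_bg > n:
        shrunk = n // 2
        warnings.warn(f"only {n} genes ranked; shrinking selection to {shrunk}/{shrunk}")
        k_top = min(k_top, shrunk)
        k_bg = min(k_bg, shrunk)
    order = ranked.sort_values("rank")
    top = set(order.index[:k_top])
    bottom = set(order.index[n - k_bg:]) if k_bg else set()
    ranked.loc[ranked.index.isin(top), "class"] = "agoTRIBE"
    ranked.loc[ranked.index.isin(bottom), "class"] = "background"
    return top, bottom
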