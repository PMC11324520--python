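"""Target derepression after global miRNA inhibition.

Count matrices are normalized between samples with a trimmed-mean-of-M-values
(TMM) scheme, low-abundance genes are removed, per-gene log2 fold changes
between the inhibited and control conditions are computed, and the fold-change
distributions of target vs background genes are compared with their ECDFs and
the DTS two-sample statistic — a variance-reweighted integral of the distance
between the two empirical cumulative distribution functions, with significance
from label permutation.

TMM convention used here: M-values are log2 ratios of raw counts against the
reference sample, so the resulting factor absorbs sequencing-depth differences
as well as composition bias, and the normalized count is simply
``count / factor`` (factors rescaled to geometric mean 1). The reference
sample is the one whose upper-quartile count fraction is closest to the mean;
trimming removes the stated fractions of extreme M and extreme A values and
the remaining M-values are averaged with inverse asymptotic-variance weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import logger


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abs_trim: float = 0.05) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    ``counts`` is genes x samples. Genes with zero counts in every sample are
    ignored (undefined in M/A space); a sample whose total is zero is an error.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    data = counts.to_numpy(dtype=float)
    totals = data.sum(axis=0)
    if np.any(totals <= 0):
        bad = counts.columns[totals <= 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    expressed = data[data.sum(axis=1) > 0]
    # reference: upper-quartile count fraction closest to the mean across samples
    f75 = np.array([np.quantile(expressed[:, j], 0.75) / totals[j]
                    for j in range(data.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.zeros(data.shape[1])
    for j in range(data.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(expressed[:, j], expressed[:, ref],
                                   totals[j], totals[ref], logratio_trim, abs_trim)
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abs_trim: float) -> float:
    both = (obs > 0) & (ref > 0)
    obs, ref = obs[both], ref[both]
    if obs.size == 0:
        return 0.0
    m = np.log2(obs) - np.log2(ref)                       # raw-count log ratio
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))      # average relative abundance
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.allclose(m, m[0]):
        return float(m[0])                                # pure depth shift, nothing to trim
    n = m.size
    m_rank = m.argsort().argsort()
    a_rank = a.argsort().argsort()
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n + 1 - (np.floor(n * abs_trim) + 1)
    keep = ((m_rank + 1 >= lo_m) & (m_rank + 1 <= hi_m)
            & (a_rank + 1 >= lo_a) & (a_rank + 1 <= hi_a))
    if not keep.any():
        keep = np.ones(n, dtype=bool)
    inv_w = 1.0 / w[keep]
    return float(np.sum(inv_w * m[keep]) / np.sum(inv_w))


@dataclass
class NormalizedExpression:
    """TMM-normalized counts (genes x samples) plus the factors that made them."""

    data: pd.DataFrame
    factors: pd.Series
    min_norm_count: float


def normalize_and_filter(counts: pd.DataFrame, factors: pd.Series,
                         min_norm_count: float = 50.0) -> NormalizedExpression:
    """Divide by the per-sample factor; drop unexpressed genes and any gene with
    a normalized count below the threshold in ANY sample."""
    norm = counts.div(factors, axis=1)
    expressed = counts.sum(axis=1) > 0
    keep = expressed & (norm >= min_norm_count).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("normalize_and_filter: removed %d of %d genes", dropped, len(counts))
    return NormalizedExpression(norm.loc[keep], factors, min_norm_count)


# ---------------------------------------------------------------------------
# Fold changes and ECDFs
# ---------------------------------------------------------------------------

def ecdf_points(values: np.ndarray) -> np.ndarray:
    """Sorted (value, cumulative fraction) pairs; last fraction is exactly 1."""
    v = np.sort(np.asarray(values, dtype=float))
    frac = np.arange(1, v.size + 1) / v.size
    return np.column_stack([v, frac])


def fold_change_ecdf(norm: NormalizedExpression, target_set: set[str],
                     background_set: set[str], test_samples: Sequence[str],
                     control_samples: Sequence[str]) -> dict:
    """Per-gene log2(mean test / mean control) for both groups, plus ECDF curves.

    Genes named in a set but absent from the filtered matrix are logged and
    skipped.
    """
    data = norm.data
    test_mean = data[list(test_samples)].mean(axis=1)
    ctrl_mean = data[list(control_samples)].mean(axis=1)
    log2fc = np.log2(test_mean / ctrl_mean)
    out: dict = {"log2fc": log2fc}
    for name, group in (("target", target_set), ("background", background_set)):
        if not group:
            raise ValueError(f"{name} set is empty")
        present = log2fc.index.intersection(sorted(group))
        missing = len(group) - len(present)
        if missing:
            logger.info("fold_change_ecdf: %d %s genes absent after filtering", missing, name)
        if len(present) == 0:
            raise ValueError(f"no {name} genes remain after expression filtering")
        values = log2fc.loc[present].to_numpy()
        out[f"{name}_log2fc"] = pd.Series(values, index=present)
        out[f"{name}_ecdf"] = ecdf_points(values)
    return out


# ---------------------------------------------------------------------------
# DTS two-sample test
# ---------------------------------------------------------------------------

def _dts_weights(pooled_sorted: np.ndarray, n_total: int):
    """Distinct pooled values, interval widths and the reweighting term.

    The statistic integrates |Ex - Ey| over the gaps between consecutive
    distinct pooled order statistics, each gap weighted by its width divided
    by sqrt(H (1 - H)) with H the pooled ECDF; boundary gaps where H is 0 or
    1 contribute nothing (H >= 1/n inside, and the H = 1 point ends the last
    gap, so no explicit zeroing is needed beyond dropping the final point).
    """
    # last occurrence index of each distinct value in the sorted pooled sample
    distinct, first_idx = np.unique(pooled_sorted, return_index=True)
    counts = np.diff(np.append(first_idx, n_total))
    last_idx = first_idx + counts - 1
    if distinct.size < 2:
        return distinct, last_idx, np.zeros(0)
    h = (last_idx[:-1] + 1) / n_total
    widths = np.diff(distinct)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = widths / np.sqrt(h * (1.0 - h))
    w[(h <= 0.0) | (h >= 1.0)] = 0.0
    return distinct, last_idx, w


def dts_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """The reweighted ECDF-distance statistic for two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    pooled_sorted = pooled[order]
    is_x_sorted = (order < x.size)[np.newaxis, :]
    distinct, last_idx, w = _dts_weights(pooled_sorted, pooled.size)
    if w.size == 0:
        return 0.0
    return float(_dts_from_labels(is_x_sorted, last_idx, w, x.size, y.size)[0])


def _dts_from_labels(is_x_sorted: np.ndarray, last_idx: np.ndarray, w: np.ndarray,
                     nx: int, ny: int) -> np.ndarray:
    """Statistic for each row of a (B, n) boolean x-membership matrix aligned
    to the sorted pooled sample."""
    cum_x = np.cumsum(is_x_sorted, axis=1)[:, last_idx[:-1]]
    ex = cum_x / nx
    ey = ((last_idx[:-1] + 1) - cum_x) / ny
    return np.abs(ex - ey) @ w


def dts_test(x: Sequence[float], y: Sequence[float], n_perm: int = 2000,
             seed: int | None = None) -> tuple[float, float]:
    """DTS statistic plus permutation p-value.

    When the number of distinct label assignments C(nx+ny, nx) does not exceed
    ``n_perm``, all assignments are enumerated and p is the exact fraction of
    assignments with a statistic at least as large as the observed one.
    Otherwise ``n_perm`` random label permutations are drawn under ``seed`` and
    the add-one Monte-Carlo estimator (1 + hits) / (1 + n_perm) is reported.
    Degenerate all-equal input yields statistic 0 and p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    pooled_sorted = pooled[order]
    n = pooled.size
    distinct, last_idx, w = _dts_weights(pooled_sorted, n)
    if w.size == 0:  # all values identical
        return 0.0, 1.0
    observed_labels = (order < x.size)[np.newaxis, :]
    observed = float(_dts_from_labels(observed_labels, last_idx, w, x.size, y.size)[0])

    if comb(n, x.size) <= n_perm:
        from itertools import combinations

        stats_all = []
        for idx in combinations(range(n), x.size):
            labels = np.zeros((1, n), dtype=bool)
            labels[0, list(idx)] = True
            stats_all.append(_dts_from_labels(labels, last_idx, w, x.size, y.size)[0])
        stats_all = np.array(stats_all)
        p = float(np.mean(stats_all >= observed - 1e-12))
        return observed, p

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, int(5e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        noise = rng.random((b, n))
        perm_idx = np.argsort(noise, axis=1)
        labels = perm_idx < x.size
        stats_b = _dts_from_labels(labels, last_idx, w, x.size, y.size)
        hits += int(np.sum(stats_b >= observed - 1e-12))
        done += b
    p = (1 + hits) / (1 + n_perm)
    return observed, float(p)
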