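"""Matched transcript-protein correlation and group-wise protein/mRNA
ratio divergence.

The per-group ratio of a pair is reported as the difference of the group
medians of the log levels, i.e. the log of the protein/mRNA ratio:
positive values mean protein-dominant expression. (Literally dividing the
two medians is numerically degenerate on centered data; a ``literal-div``
mode keeps that reading available.)
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MatchedPairTable

__all__ = ["RatioTable", "pair_correlations", "group_ratio", "ratio_shift_test"]


@dataclass
class RatioTable:
    """Per-pair per-group log protein/mRNA ratios plus per-sample medians."""

    per_pair: pd.DataFrame
    per_sample: pd.Series
    mode: str = "log-diff"


def pair_correlations(pairs: MatchedPairTable):
    """Per-pair Pearson r and p across samples, plus the median r.

    p-values come from the t transform of r with n-2 degrees of freedom.
    Zero-variance pairs get NaN with a warning and are excluded from the
    median.
    """
    X = pairs.mrna_values.to_numpy(dtype=float)
    Y = pairs.protein_values.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    bad = (sx < 1e-12) | (sy < 1e-12)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance pair(s); correlation undefined", stacklevel=2)
    denom = np.where(bad, 1.0, sx * sy)
    r = np.where(bad, np.nan, (Xc * Yc).sum(axis=0) / denom)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(np.isnan(r), np.nan, p)
    table = pd.DataFrame({"pair_id": pairs.pair_ids, "r": r, "p": p})
    return table, float(np.nanmedian(r))


def group_ratio(pairs: MatchedPairTable, labels, mode: str = "log-diff") -> RatioTable:
    """Per-group protein/mRNA ratio per pair, plus per-sample median ratios.

    ``log-diff`` (default) reports median(log protein) - median(log mRNA)
    within each group; ``literal-div`` divides the two medians instead.
    """
    labels = pd.Series(labels).reindex(pairs.sample_ids)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2 or labels.isna().any():
        raise ValueError("labels must assign every sample to one of exactly 2 groups")
    if mode not in ("log-diff", "literal-div"):
        raise ValueError("mode must be 'log-diff' or 'literal-div'")
    out = {"pair_id": pairs.pair_ids}
    for g in groups:
        m = (labels == g).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"group {g} has no samples")
        med_p = np.median(pairs.protein_values.to_numpy()[m], axis=0)
        med_m = np.median(pairs.mrna_values.to_numpy()[m], axis=0)
        if mode == "log-diff":
            out[f"ratio_{g}"] = med_p - med_m
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[f"ratio_{g}"] = med_p / med_m
    per_sample = pd.Series(
        np.median(pairs.protein_values.to_numpy() - pairs.mrna_values.to_numpy(), axis=1),
        index=pairs.sample_ids,
        name="median_log_ratio",
    )
    return RatioTable(per_pair=pd.DataFrame(out), per_sample=per_sample, mode=mode)


def _exact_mw_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all group assignments on midranks."""
    n = len(pooled_ranks)
    mu = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = pooled_ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            count += 1
    return count / total


def ratio_shift_test(x, y):
    """Mann-Whitney U test (two-sided) between two samples.

    Exact p by full enumeration of group assignments over midranks when
    ``min(n1, n2) <= 8``; otherwise the normal approximation with tie and
    continuity corrections. Returns ``(U, p)`` with U counted for the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    if min(n1, n2) <= 8:
        p = _exact_mw_p(ranks, n1, u1)
        return float(u1), float(p)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return float(u1), float(p)
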