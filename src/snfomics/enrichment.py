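"""Gene-set enrichment: preranked GSEA on t statistics, enrichment-map
edges, and single-sample signature scoring.

The enrichment score is the classical weighted Kolmogorov-Smirnov running
sum: walking down the ranking, in-set features increment the sum in
proportion to ``|stat|^weight`` (normalised over in-set features) and
out-of-set features decrement it uniformly; ES is the maximum deviation of
the walk. Significance for the preranked mode uses a gene-label permutation
null (the only null a preranked list admits), with the add-one rule so
``p >= 1/(n_permutations+1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, OmicMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_features",
    "enrichment_score",
    "preranked_gsea",
    "enrichment_map_edges",
    "ssgsea_score",
]


@dataclass
class RankedList:
    """Features ordered by a ranking statistic, descending; ties broken by
    feature id so the order is strict and reproducible."""

    feature_ids: list[str]
    statistics: np.ndarray

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        if len(self.feature_ids) != len(self.statistics):
            raise ValueError("ids and statistics must have equal length")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float
    size: int
    leading_edge: list[str] = field(default_factory=list)


def rank_features(feature_ids, statistics) -> RankedList:
    """Descending-statistic ranking with feature-id tie-breaking."""
    stats = np.asarray(statistics, dtype=float)
    order = sorted(range(len(stats)), key=lambda i: (-stats[i], str(feature_ids[i])))
    return RankedList([feature_ids[i] for i in order], stats[order])


def _es_rows(stat_rows: np.ndarray, mask_rows: np.ndarray, weight: float):
    """Vectorised ES for many (ranking, set-mask) rows at once.

    ``stat_rows`` holds ranking statistics already in ranked order per row;
    ``mask_rows`` flags in-set positions. Returns (es, peak_index) arrays.
    """
    stat_rows = np.atleast_2d(np.asarray(stat_rows, dtype=float))
    mask_rows = np.atleast_2d(np.asarray(mask_rows, dtype=bool))
    n = stat_rows.shape[1]
    w = np.abs(stat_rows) ** weight * mask_rows
    wsum = w.sum(axis=1, keepdims=True)
    # degenerate all-zero hit weights fall back to equal hit weights
    fallback = wsum[:, 0] == 0
    if fallback.any():
        w[fallback] = mask_rows[fallback].astype(float)
        wsum = w.sum(axis=1, keepdims=True)
    n_hit = mask_rows.sum(axis=1, keepdims=True)
    n_miss = np.maximum(n - n_hit, 1)
    running = np.cumsum(w / wsum - (~mask_rows) / n_miss, axis=1)
    peak = np.argmax(np.abs(running), axis=1)
    es = running[np.arange(running.shape[0]), peak]
    return es, peak


def enrichment_score(ranked: RankedList, members, weight: float = 1.0):
    """Observed ES of one set plus its leading-edge members."""
    mask = np.isin(ranked.feature_ids, list(members))
    es, peak = _es_rows(ranked.statistics, mask, weight)
    es, peak = float(es[0]), int(peak[0])
    ids = np.asarray(ranked.feature_ids)
    if es >= 0:
        leading = list(ids[: peak + 1][mask[: peak + 1]])
    else:
        leading = list(ids[peak + 1 :][mask[peak + 1 :]])
    return es, leading


def preranked_gsea(
    ranked: RankedList,
    sets: GeneSetCollection,
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    p_cut: float = 0.0005,
    q_cut: float = 0.03,
    min_size: int = 10,
    max_size: int = 500,
    pass_through: bool = False,
) -> list[EnrichmentResult]:
    """Preranked GSEA with a gene-label permutation null.

    Sets are first intersected with the ranked universe; sets smaller than
    ``min_size`` or larger than ``max_size`` after intersection are skipped
    with a log entry. Nominal p is one-sided within the sign of the
    observed ES, NES divides ES by the mean |null ES| of matching sign, and
    BH q-values are computed within sign. Unless ``pass_through`` is set,
    only results with ``p <= p_cut`` and ``q <= q_cut`` are returned.
    """
    rng = np.random.default_rng(seed)
    universe = set(ranked.feature_ids)
    n = len(ranked.feature_ids)
    stats = ranked.statistics

    records = []
    for s in sets:
        members = [m for m in s.members if m in universe]
        if not (min_size <= len(members) <= max_size):
            logger.info("skipping set '%s' (size %d after intersection)", s.name, len(members))
            continue
        es, leading = enrichment_score(ranked, members, weight)
        m = len(members)
        # gene-label permutation: random positions of the same set size
        pick = rng.random((n_permutations, n)).argsort(axis=1)[:, :m]
        null_mask = np.zeros((n_permutations, n), dtype=bool)
        null_mask[np.arange(n_permutations)[:, None], pick] = True
        null_es, _ = _es_rows(np.broadcast_to(stats, (n_permutations, n)), null_mask, weight)
        if es >= 0:
            same = null_es[null_es >= 0]
            p = (1 + int((same >= es).sum())) / (1 + len(same))
        else:
            same = null_es[null_es < 0]
            p = (1 + int((same <= es).sum())) / (1 + len(same))
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        records.append(EnrichmentResult(s.name, es, float(nes), float(p), np.nan, m, leading))

    # BH within sign
    for sign in (1, -1):
        idx = [i for i, r in enumerate(records) if (r.es >= 0) == (sign == 1)]
        if idx:
            _, q, _, _ = multipletests([records[i].p for i in idx], method="fdr_bh")
            for i, qi in zip(idx, q):
                records[i].q = float(qi)
    if pass_through:
        return records
    return [r for r in records if r.p <= p_cut and r.q <= q_cut]


def enrichment_map_edges(results: list[EnrichmentResult], sets: GeneSetCollection, similarity_cutoff: float = 0.5) -> pd.DataFrame:
    """Overlap-coefficient edges between retained sets.

    An edge connects two sets when ``|A ∩ B| / min(|A|, |B|)`` reaches the
    cutoff (default 0.5: the sets share at least half of the smaller set).
    """
    names = [r.set_name for r in results]
    members = {nm: set(sets[nm].members) for nm in names}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = members[names[i]], members[names[j]]
            denom = min(len(a), len(b))
            coef = len(a & b) / denom if denom else 0.0
            if coef >= similarity_cutoff:
                rows.append((names[i], names[j], coef))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def ssgsea_score(matrix: OmicMatrix, feature_set, weight: float = 0.0, min_size: int = 5) -> pd.Series:
    """Single-sample enrichment score of one feature set per sample.

    Per sample, features are ranked by descending expression (ties broken
    by feature id) and the score integrates the difference between the
    running in-set and out-of-set cumulative distributions over the
    ranking, normalised by the out-of-set count; in-set steps may be
    rank-weighted via ``weight`` (default 0: plain ECDF difference, which
    is mean-zero under random interleaving). Scores are comparable within
    one run only; provenance labels them "ssgsea-like".
    """
    members = [m for m in feature_set if m in set(matrix.feature_ids)]
    if len(members) < min_size:
        raise ValueError(f"feature set has {len(members)} member(s) in the matrix; need >= {min_size}")
    ids = np.asarray(matrix.feature_ids)
    member_mask = np.isin(ids, members)
    n = len(ids)
    n_in = member_mask.sum()
    n_out = n - n_in
    id_rank = np.argsort(np.argsort(ids))  # lexicographic tie-break key
    scores = {}
    for sample in matrix.sample_ids:
        vals = matrix.values[sample].to_numpy(dtype=float)
        order = np.lexsort((id_rank, -vals))
        in_ranked = member_mask[order]
        pos_w = (np.arange(n, 0, -1, dtype=float)) ** weight
        hit_w = pos_w * in_ranked
        f_in = np.cumsum(hit_w) / hit_w.sum()
        f_out = np.cumsum(~in_ranked) / n_out
        scores[sample] = float((f_in - f_out).sum() / n_out)
    return pd.Series(scores, name="score")
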