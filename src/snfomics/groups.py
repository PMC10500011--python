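"""Differential signatures, semi-supervised group extension, and
cross-cohort subclass association (submap).

Group convention throughout: the two group labels are taken in sorted
order, and log2 fold changes are reported as (first group - second group)
on the log2 scale, so positive values mean "up in the first sorted group".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .enrichment import _es_rows
from .io import OmicMatrix
from .preprocess import log_and_zscore

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialTable",
    "FeatureSignature",
    "SubmapResult",
    "differential_features",
    "build_signature",
    "extend_groups_hcl",
    "submap",
]


@dataclass
class FeatureSignature:
    """Ordered up/down marker lists with the thresholds that produced them."""

    up_features: list[str]
    down_features: list[str]
    n_per_direction: int
    layer: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_features) & set(self.down_features):
            raise ValueError("up and down lists must be disjoint")

    @property
    def features(self) -> list[str]:
        return self.up_features + self.down_features


@dataclass
class SubmapResult:
    """FDR-adjusted subclass-association matrix between two cohorts."""

    sa_matrix: pd.DataFrame
    nominal_p: pd.DataFrame
    directional_p: dict
    n_markers: int
    n_permutations: int


#: alias so the differential output reads as a domain type
DifferentialTable = pd.DataFrame


def _two_groups(labels) -> tuple[pd.Series, list]:
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    return labels, groups


def differential_features(matrix: OmicMatrix, labels, p_thresh: float = 0.05, fc_thresh: float = 2.0) -> DifferentialTable:
    """Per-feature Welch t-test between two groups on log2 values.

    Returns a table sorted by ascending p (ties by feature id) with group
    means, log2 fold change (first sorted group minus second), linear fold
    change, t, p, BH q and a significance flag
    ``p <= p_thresh AND |FC| >= fc_thresh``.
    """
    labels, groups = _two_groups(labels)
    labels = labels.reindex(matrix.sample_ids)
    m1 = labels == groups[0]
    m2 = labels == groups[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    V = matrix.values.to_numpy(dtype=float)
    A, B = V[:, m1.to_numpy()], V[:, m2.to_numpy()]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    # constant features: equal means are a null feature (t=0, p=1); zero
    # variance with different means is infinitely significant (p=0)
    nan_t = np.isnan(t)
    t = np.where(nan_t, 0.0, t)
    p = np.where(nan_t, 1.0, np.where(np.isinf(t), 0.0, p))
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    table = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            f"mean_{groups[0]}": A.mean(axis=1),
            f"mean_{groups[1]}": B.mean(axis=1),
            "log2_fc": log2fc,
            "fold_change": 2.0**log2fc,
            "t": t,
            "p": p,
        }
    )
    table = table.sort_values(["p", "feature_id"], kind="stable").reset_index(drop=True)
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    table["significant"] = (table["p"] <= p_thresh) & (np.abs(table["log2_fc"]) >= np.log2(fc_thresh))
    table.attrs["groups"] = groups
    return table


def build_signature(table: DifferentialTable, n_per_direction: int, layer: str = "") -> FeatureSignature:
    """Top up/down markers by p among significant features only."""
    if not table["p"].is_monotonic_increasing:
        raise ValueError("differential table must be sorted by ascending p")
    sig = table[table["significant"]]
    up = list(sig.loc[sig["log2_fc"] > 0, "feature_id"].head(n_per_direction))
    down = list(sig.loc[sig["log2_fc"] < 0, "feature_id"].head(n_per_direction))
    for name, lst in (("up", up), ("down", down)):
        if len(lst) < n_per_direction:
            warnings.warn(
                f"only {len(lst)} significant {name}-regulated feature(s) available "
                f"(requested {n_per_direction})",
                stacklevel=2,
            )
    return FeatureSignature(
        up_features=up,
        down_features=down,
        n_per_direction=n_per_direction,
        layer=layer,
        provenance={"n_significant": int(table["significant"].sum())},
    )


def extend_groups_hcl(matrix: OmicMatrix, signature: FeatureSignature, core_labels) -> pd.Series:
    """Extend core group labels to all samples by hierarchical clustering.

    Restricts to the signature features, z-scores them, computes the
    Pearson-dissimilarity (1 - r) between samples, agglomerates with
    average linkage, cuts the tree into two clusters, and names each
    cluster after the group holding the majority of its core-labelled
    samples. Deterministic: linkage has no randomness and correlation ties
    are resolved by sample order inside the linkage algorithm.
    """
    core_labels, groups = _two_groups(core_labels)
    if (core_labels.value_counts() < 2).any():
        raise ValueError("core labels must cover at least 2 samples per group")
    missing = [f for f in signature.features if f not in set(matrix.feature_ids)]
    if missing:
        raise ValueError(f"signature feature(s) absent from matrix: {', '.join(missing[:5])}")
    if not signature.features:
        raise ValueError("signature is empty; no significant features to extend with")
    sub = log_and_zscore(matrix.subset_features(signature.features))
    X = sub.values.to_numpy()  # features x samples
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    corr = np.nan_to_num(corr, nan=0.0)  # constant sample profiles: treat as uncorrelated
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    cut = fcluster(Z, t=2, criterion="maxclust")

    samples = pd.Index(matrix.sample_ids)
    assigned = {}
    for cluster_id in np.unique(cut):
        members = samples[cut == cluster_id]
        cores = core_labels.reindex(members).dropna()
        if cores.empty:
            raise ValueError(
                f"cluster {cluster_id} contains no core-labelled sample; "
                "lower n_per_direction or provide more core labels"
            )
        assigned[cluster_id] = cores.value_counts().idxmax()
    if len(set(assigned.values())) < 2:
        raise ValueError("both clusters map to the same core group; groups are not separable")
    return pd.Series([assigned[c] for c in cut], index=samples, name="group")


def _welch_t_rows(V: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Welch t statistics (group-in-mask minus rest) for many label masks.

    ``V`` is features x samples; ``masks`` is (n_masks, n_samples) boolean.
    Returns (n_masks, n_features).
    """
    masks = np.atleast_2d(masks).astype(float)
    n1 = masks.sum(axis=1)
    n2 = masks.shape[1] - n1
    tot = V.sum(axis=1)
    tot_sq = (V**2).sum(axis=1)
    s1 = V @ masks.T  # features x masks
    sq1 = (V**2) @ masks.T
    m1 = s1 / n1
    m2 = (tot[:, None] - s1) / n2
    var1 = (sq1 - n1 * m1**2) / np.maximum(n1 - 1, 1)
    var2 = ((tot_sq[:, None] - sq1) - n2 * m2**2) / np.maximum(n2 - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(var1 / n1 + var2 / n2)
    return np.nan_to_num(t).T


def submap(
    matrix_a: OmicMatrix,
    labels_a,
    matrix_b: OmicMatrix,
    labels_b,
    n_markers: int = 200,
    n_permutations: int = 1000,
    seed: int = 0,
) -> SubmapResult:
    """Subclass association between two 2-group cohorts.

    For every group g in cohort A, its top up-regulated markers (smallest
    p, capped at ``n_markers``) are scored against cohort B's g'-vs-rest
    t-statistic ranking with the weighted KS enrichment score; the null
    shuffles B's sample labels. The procedure is run in both directions,
    one-sided permutation p-values are combined with Fisher's method, and
    the subclass-association matrix is BH-FDR adjusted. ``nominal_p``
    preserves the pre-FDR combined values and ``directional_p`` the raw
    one-directional permutation p-values.
    """
    shared = [f for f in matrix_a.feature_ids if f in set(matrix_b.feature_ids)]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared feature(s); need >= 50")
    A = matrix_a.subset_features(shared)
    B = matrix_b.subset_features(shared)
    labels_a, groups_a = _two_groups(labels_a)
    labels_b, groups_b = _two_groups(labels_b)
    rng = np.random.default_rng(seed)

    def _markers(matrix, labels, groups):
        table = differential_features(matrix, labels, p_thresh=1.0, fc_thresh=1.0)
        out = {}
        for g in groups:
            up_col = f"mean_{g}"
            other = [c for c in groups if c != g][0]
            up = table[table[up_col] > table[f"mean_{other}"]]
            out[g] = list(up["feature_id"].head(n_markers))
        return out

    def _direction(src_markers, tgt_matrix, tgt_labels, tgt_groups):
        """p[src group g][tgt group h] of g's markers enriching h's ranking."""
        V = tgt_matrix.values.to_numpy(dtype=float)
        ids = np.asarray(tgt_matrix.feature_ids)
        lab = tgt_labels.reindex(tgt_matrix.sample_ids).to_numpy()
        id_rank = np.argsort(np.argsort(ids))
        perm_labels = np.array([rng.permutation(lab) for _ in range(n_permutations)])
        result = {}
        for h in tgt_groups:
            obs_mask = (lab == h)[None, :]
            masks = np.vstack([obs_mask, perm_labels == h])
            t_rows = _welch_t_rows(V, masks)  # (1 + n_perm) x features
            order = np.lexsort((np.broadcast_to(id_rank, t_rows.shape), -t_rows), axis=1)
            stat_rows = np.take_along_axis(t_rows, order, axis=1)
            for g, markers in src_markers.items():
                member = np.isin(ids, markers)
                mask_rows = np.take_along_axis(np.broadcast_to(member, t_rows.shape), order, axis=1)
                es, _ = _es_rows(stat_rows, mask_rows, weight=1.0)
                p = (1 + int((es[1:] >= es[0]).sum())) / (n_permutations + 1)
                result[(g, h)] = p
        return result

    markers_a = _markers(A, labels_a, groups_a)
    markers_b = _markers(B, labels_b, groups_b)
    p_ab = _direction(markers_a, B, labels_b, groups_b)  # (a_group, b_group)
    p_ba = _direction(markers_b, A, labels_a, groups_a)  # (b_group, a_group)

    combined = pd.DataFrame(index=groups_a, columns=groups_b, dtype=float)
    for g in groups_a:
        for h in groups_b:
            x2 = -2.0 * (np.log(p_ab[(g, h)]) + np.log(p_ba[(h, g)]))
            combined.loc[g, h] = stats.chi2.sf(x2, df=4)
    flat = combined.to_numpy().ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    sa = pd.DataFrame(q.reshape(combined.shape), index=groups_a, columns=groups_b)
    return SubmapResult(
        sa_matrix=sa,
        nominal_p=combined,
        directional_p={"a_to_b": p_ab, "b_to_a": p_ba},
        n_markers=n_markers,
        n_permutations=n_permutations,
    )
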