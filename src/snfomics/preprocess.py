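"""Data reduction and normalisation applied before integration.

Covers the proteomics retention filter (minimum detected peptide ratios,
no missing values), feature-wise z-scoring on the log scale, and the
construction of the matched transcript-protein pair table used by the
posttranscriptional analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OmicMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinQuantTable",
    "MatchedPairTable",
    "filter_proteins",
    "log_and_zscore",
    "match_pairs",
]


@dataclass
class ProteinQuantTable:
    """Raw protein quantification: abundances plus per-protein peptide evidence.

    ``abundances`` is features x samples (NaN = missing); ``peptide_counts``
    is the number of detected peptide ratios per protein, aligned to the
    abundance rows.
    """

    abundances: pd.DataFrame
    peptide_counts: pd.Series

    def __post_init__(self) -> None:
        self.abundances = self.abundances.astype(float)
        self.peptide_counts = self.peptide_counts.astype(int)
        if not self.abundances.index.equals(self.peptide_counts.index):
            raise ValueError("peptide_counts must be aligned to abundance rows")
        if (self.peptide_counts < 0).any():
            raise ValueError("peptide counts must be non-negative")


@dataclass
class MatchedPairTable:
    """Aligned transcript/protein values for gene products in both layers.

    Both blocks are samples x pairs, log scale and per-pair centered across
    samples; the sample order is identical in the two blocks and no missing
    values remain.
    """

    mrna_values: pd.DataFrame
    protein_values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.mrna_values.index.equals(self.protein_values.index):
            raise ValueError("sample order must match between blocks")
        if not self.mrna_values.columns.equals(self.protein_values.columns):
            raise ValueError("pair ids must match between blocks")
        if self.mrna_values.isna().any().any() or self.protein_values.isna().any().any():
            raise ValueError("matched pair table must not contain missing values")

    @property
    def pair_ids(self) -> list[str]:
        return list(self.mrna_values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mrna_values.index)

    @property
    def n_pairs(self) -> int:
        return self.mrna_values.shape[1]


def filter_proteins(raw: ProteinQuantTable, min_peptides: int = 3, require_complete: bool = True) -> OmicMatrix:
    """Retention filter: keep proteins quantified by at least ``min_peptides``
    detected peptide ratios and (optionally) with no missing abundance.
    """
    keep = raw.peptide_counts >= min_peptides
    if require_complete:
        keep &= raw.abundances.notna().all(axis=1)
    retained = raw.abundances.loc[keep]
    logger.info("filter_proteins: retained %d / %d proteins", len(retained), len(raw.abundances))
    if retained.empty:
        warnings.warn("protein retention filter removed every protein", stacklevel=2)
    return OmicMatrix("protein", retained.copy(), is_log=True)


def log_and_zscore(matrix: OmicMatrix, log_base: float = 2.0, pseudocount: float = 1.0) -> OmicMatrix:
    """Per-feature standardisation to mean 0, population sd 1.

    Linear-scale input is first transformed with ``log(x + pseudocount)``;
    already-log input is standardised as-is. Constant features become
    all-zero rows with a warning.
    """
    values = matrix.values.to_numpy(dtype=float, copy=True)
    if not matrix.is_log:
        if np.nanmin(values) < 0:
            raise ValueError("negative values on a linear scale cannot be log-transformed")
        values = np.log(values + pseudocount) / np.log(log_base)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, keepdims=True)  # population sd
    constant = (sd < 1e-12).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) set to all-zero", stacklevel=2)
    sd[sd < 1e-12] = 1.0
    out = (values - mean) / sd
    out[constant, :] = 0.0
    return OmicMatrix(
        matrix.layer_name,
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        is_log=True,
    )


def match_pairs(mrna: OmicMatrix, protein: OmicMatrix, id_map: dict[str, str] | None = None, pseudocount: float = 1.0) -> MatchedPairTable:
    """Pair gene products measured in both layers.

    ``id_map`` maps protein feature ids to transcript feature ids when the
    two layers use different id schemes. Both blocks are log2-transformed
    (when not already log) and centered per pair across samples. Samples
    must already be aligned (see :func:`snfomics.io.align_cohort`). Pairs
    with any missing value in either layer are dropped with a warning.
    """
    if list(mrna.sample_ids) != list(protein.sample_ids):
        raise ValueError("layers must share an identical sample order; run align_cohort first")

    prot_ids = protein.feature_ids
    mapped = [id_map.get(p, p) if id_map else p for p in prot_ids]
    mrna_set = set(mrna.feature_ids)
    pairs, seen = [], set()
    for p, g in zip(prot_ids, mapped):
        if g in mrna_set and g not in seen:
            seen.add(g)
            pairs.append((p, g))
    if not pairs:
        raise ValueError("no gene products shared between the two layers")

    def _log(m: OmicMatrix) -> pd.DataFrame:
        v = m.values
        if m.is_log:
            return v.astype(float)
        if np.nanmin(v.to_numpy()) < 0:
            raise ValueError("negative values on a linear scale cannot be log-transformed")
        return np.log2(v + pseudocount)

    mrna_log = _log(mrna)
    prot_log = _log(protein)
    pair_ids = [g for _, g in pairs]
    m_block = mrna_log.loc[pair_ids].T
    p_block = prot_log.loc[[p for p, _ in pairs]].T
    p_block.columns = pair_ids

    complete = m_block.notna().all(axis=0) & p_block.notna().all(axis=0)
    if not complete.all():
        warnings.warn(f"dropped {int((~complete).sum())} pair(s) with missing values", stacklevel=2)
    m_block = m_block.loc[:, complete]
    p_block = p_block.loc[:, complete]
    logger.info("match_pairs: %d matched pair(s)", m_block.shape[1])

    # per-pair centering across samples
    m_block = m_block - m_block.mean(axis=0)
    p_block = p_block - p_block.mean(axis=0)
    return MatchedPairTable(mrna_values=m_block, protein_values=p_block)
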