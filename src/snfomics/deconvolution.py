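"""Cell-type fraction estimation from bulk expression.

Per sample, bulk expression over the signature genes is modelled as a
non-negative linear mixture of reference cell-type profiles; coefficients
are fit by non-negative least squares on the linear abundance scale and
normalised to sum to one (relative fractions). Provenance labels the
method "nnls". Group contrasts on the estimated fractions use the
Mann-Whitney test with BH correction across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .io import OmicMatrix, SignatureMatrix
from .ratios import ratio_shift_test

__all__ = ["DeconvolutionResult", "estimate_fractions", "compare_fractions"]


@dataclass
class DeconvolutionResult:
    """Estimated fractions (samples x cell types, rows sum to 1) plus the
    per-sample NNLS residual norm."""

    fractions: pd.DataFrame
    residuals: pd.Series
    method: str = "nnls"


def _collinear_types(profiles: np.ndarray, cell_types: list[str]) -> list[str]:
    """Name the cell types involved in a rank deficiency."""
    rank = np.linalg.matrix_rank(profiles)
    if rank >= profiles.shape[1]:
        return []
    involved = []
    for j, ct in enumerate(cell_types):
        others = np.delete(profiles, j, axis=1)
        coef, res = np.linalg.lstsq(others, profiles[:, j], rcond=None)[:2]
        resid = res[0] if len(res) else np.sum((others @ coef - profiles[:, j]) ** 2)
        if resid < 1e-10 * max(1.0, np.sum(profiles[:, j] ** 2)):
            involved.append(ct)
    return involved or cell_types


def estimate_fractions(matrix: OmicMatrix, sig: SignatureMatrix) -> DeconvolutionResult:
    """Relative cell-type fractions per bulk sample via NNLS.

    Log-scale input is de-logged (2**x) first: mixtures are linear in
    abundance space. Requires at least 5 features shared with the
    signature matrix and a full-rank signature.
    """
    shared = [f for f in sig.feature_ids if f in set(matrix.feature_ids)]
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} feature(s) shared with the signature matrix; need >= 5")
    profiles = sig.profiles.loc[shared].to_numpy(dtype=float)
    cell_types = sig.cell_types
    bad = _collinear_types(profiles, cell_types)
    if bad:
        raise ValueError(f"signature matrix is rank-deficient; collinear cell type(s): {', '.join(bad)}")
    values = matrix.values.loc[shared].to_numpy(dtype=float)
    if matrix.is_log:
        values = 2.0**values
    fracs = np.zeros((matrix.n_samples, len(cell_types)))
    resid = np.zeros(matrix.n_samples)
    for i in range(matrix.n_samples):
        coef, r = nnls(profiles, values[:, i])
        total = coef.sum()
        fracs[i] = coef / total if total > 0 else 1.0 / len(cell_types)
        resid[i] = r
    return DeconvolutionResult(
        fractions=pd.DataFrame(fracs, index=matrix.sample_ids, columns=cell_types),
        residuals=pd.Series(resid, index=matrix.sample_ids, name="residual_norm"),
    )


def compare_fractions(result: DeconvolutionResult, labels) -> pd.DataFrame:
    """Per-cell-type Mann-Whitney group contrast with BH correction."""
    labels = pd.Series(labels).reindex(result.fractions.index)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2 or labels.isna().any():
        raise ValueError("labels must assign every sample to one of exactly 2 groups")
    rows = []
    for ct in result.fractions.columns:
        x = result.fractions.loc[labels == groups[0], ct]
        y = result.fractions.loc[labels == groups[1], ct]
        u, p = ratio_shift_test(x, y)
        rows.append({"cell_type": ct, f"median_{groups[0]}": x.median(), f"median_{groups[1]}": y.median(), "U": u, "p": p})
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p"], method="fdr_bh")
    table["q"] = q
    return table
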