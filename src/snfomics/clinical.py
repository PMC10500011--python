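"""Clinical association statistics: Kaplan-Meier progression-free
survival, the log-rank test, and categorical trait association.

Conventions: tied event times use the standard pooled risk-set treatment;
a censoring recorded at an event time is counted after the event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = ["SurvivalTable", "km_curves", "logrank_test", "categorical_association"]


@dataclass
class SurvivalTable:
    """Time (months), event indicator (0/1) and group per subject."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("time", "event", "group"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column '{col}'")
        df["time"] = df["time"].astype(float)
        if (df["time"] < 0).any():
            raise ValueError("time must be non-negative")
        ev = df["event"].astype(float)
        if not ev.isin([0.0, 1.0]).all():
            raise ValueError("event must be 0 or 1")
        df["event"] = ev.astype(int)
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_clinical(cls, clinical) -> "SurvivalTable":
        df = clinical.data
        if "group" not in df.columns:
            raise ValueError("clinical table has no group column")
        return cls(pd.DataFrame({"time": df["pfs_time"], "event": df["pfs_event"], "group": df["group"]}))


def km_curves(table: SurvivalTable) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns, per group, a step table with the distinct observed times, the
    number at risk, the survival estimate and the censoring count at each
    time. Survival is non-increasing from 1.0; with no events the curve is
    flat at 1.0.
    """
    out = {}
    for g, sub in table.data.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        ev = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[str(g)] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
                "events": ev["observed"].to_numpy(dtype=int),
                "censored": ev["censored"].to_numpy(dtype=int),
                "survival": surv.reindex(ev.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def logrank_test(table: SurvivalTable):
    """Two-group log-rank test: returns (chi-square statistic, p)."""
    groups = sorted(table.data["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(groups)}")
    for g in groups:
        if (table.data["group"] == g).sum() == 0:
            raise ValueError(f"group {g} has no subjects")
    if table.data["event"].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(table.data["time"], table.data["group"], table.data["event"])
    return float(res.test_statistic), float(res.p_value)


def categorical_association(counts):
    """Association test for a 2 x k contingency table.

    2x2 tables use the chi-square test with continuity correction, except
    when any expected count is below 5, where Fisher's exact
    (hypergeometric) test is used automatically; 2xk tables use the plain
    chi-square test. Returns ``(statistic, p, method)``; for Fisher's test
    the statistic is the sample odds ratio.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = np.round(counts).astype(int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero contingency table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    if counts.shape == (2, 2):
        if (expected < 5).any():
            odds, p = stats.fisher_exact(counts, alternative="two-sided")
            return float(odds), float(p), "fisher-exact"
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=True)
        return float(chi2), float(p), "chi-square-yates"
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p), "chi-square"
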